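"""Morph-contact algorithm for sliding joint-capsule interfaces.

Pipeline: segment the capsule contour into proximal / distal / interior /
exterior node sets, preliminarily morph it from a reduced set of bone
landmarks, detect bone-node penetrations via signed distance and
orientation flips, pull the associated capsule patches outward along their
normals until penetration-free, refine the interface by minimizing a
Chamfer + edge-length-consistency + normal-coherence loss, and finally
TPS-deform the enclosed flesh from the boundary landmarks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import PenetrationError, ValidationError
from .fe_model_io import FEModel
from .proximity import closest_points, signed_distance
from .surface import TriMesh
from .tps_morph import apply_tps, farthest_point_subsample, fit_tps

__all__ = [
    "CapsuleSegmentation",
    "PenetrationReport",
    "segment_capsule",
    "reduced_bone_landmarks",
    "preliminary_morph",
    "detect_penetrations",
    "resolve_penetrations",
    "refine_interface",
    "deform_soft_tissue",
    "chamfer_distance",
    "edge_length_cv",
]


@dataclass
class CapsuleSegmentation:
    """Disjoint capsule-surface node sets (vertex indices)."""

    proximal_nodes: np.ndarray
    distal_nodes: np.ndarray
    interior_nodes: np.ndarray
    exterior_nodes: np.ndarray

    def validate(self, n_vertices: int) -> None:
        sets = [set(self.proximal_nodes.tolist()),
                set(self.distal_nodes.tolist()),
                set(self.interior_nodes.tolist()),
                set(self.exterior_nodes.tolist())]
        total = 0
        union: set = set()
        for s in sets:
            total += len(s)
            union |= s
        if total != len(union):
            raise ValidationError("capsule segments are not pairwise disjoint")
        if union != set(range(n_vertices)):
            raise ValidationError("capsule segments do not cover all nodes")

    @property
    def fixed_nodes(self) -> np.ndarray:
        return np.concatenate([self.proximal_nodes, self.distal_nodes])


@dataclass
class PenetrationReport:
    """Bone nodes found inside the capsule surface.

    ``bone`` is kept so resolution can re-detect against the same mesh.
    """

    penetrating_nodes: np.ndarray  # bone vertex indices
    signed_depths: np.ndarray  # negative values, mm
    nearest_faces: np.ndarray  # capsule face indices
    bone: Optional[TriMesh] = None

    def __len__(self) -> int:
        return len(self.penetrating_nodes)

    @property
    def is_empty(self) -> bool:
        return len(self.penetrating_nodes) == 0

    def export_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node,depth_mm,nearest_face\n")
            for n, d, f in zip(self.penetrating_nodes, self.signed_depths,
                               self.nearest_faces):
                fh.write(f"{n},{d:.9g},{f}\n")


# ----------------------------------------------------------------------

def segment_capsule(capsule: TriMesh, femur: TriMesh, tibia: TriMesh,
                    tol: float = 1.0) -> CapsuleSegmentation:
    """Classify capsule nodes into the four contour segments.

    Nodes within ``tol`` of the femur surface are proximal, within ``tol``
    of the tibia distal (ties go to the nearer bone, with a warning).  Of
    the rest, nodes whose outward capsule normal points toward the nearest
    bone are interior (bone-facing wall); the others exterior.
    """
    pts = capsule.vertices
    d_f = closest_points(femur, pts)
    d_t = closest_points(tibia, pts)
    near_f = d_f[0] <= tol
    near_t = d_t[0] <= tol
    both = near_f & near_t
    if np.any(both):
        warnings.warn(
            f"{int(both.sum())} capsule nodes within tol of both bones; "
            "assigned to the nearer",
            RuntimeWarning,
        )
    proximal = near_f & (~both | (d_f[0] <= d_t[0]))
    distal = near_t & ~proximal
    rest = ~(proximal | distal)

    nearer_cp = np.where((d_f[0] <= d_t[0])[:, None], d_f[1], d_t[1])
    to_bone = nearer_cp - pts
    norms = np.linalg.norm(to_bone, axis=1)
    norms[norms == 0] = 1.0
    to_bone /= norms[:, None]
    bone_facing = np.einsum("ij,ij->i", capsule.vertex_normals, to_bone) > 0.0
    interior = rest & bone_facing
    exterior = rest & ~bone_facing

    seg = CapsuleSegmentation(
        proximal_nodes=np.nonzero(proximal)[0],
        distal_nodes=np.nonzero(distal)[0],
        interior_nodes=np.nonzero(interior)[0],
        exterior_nodes=np.nonzero(exterior)[0],
    )
    seg.validate(capsule.n_vertices)
    return seg


def reduced_bone_landmarks(bone: TriMesh, transform, other_bone_center,
                           fraction: float = 0.1, seed: int = 0,
                           exclude_cos: float = 0.5):
    """Reduced landmark pairs for the preliminary capsule morph.

    Farthest-point subsample (~``fraction`` of bone surface nodes) excluding
    joint-space-facing vertices — those whose outward normal points toward
    the other bone (cos > ``exclude_cos``) — since bone segments moving into
    the joint space are the known failure source of a naive morph.

    Returns (source (k, 3), target (k, 3) = transform applied).
    """
    pts = bone.vertices
    to_other = np.asarray(other_bone_center, float) - pts
    nrm = np.linalg.norm(to_other, axis=1)
    nrm[nrm == 0] = 1.0
    to_other /= nrm[:, None]
    facing = np.einsum("ij,ij->i", bone.vertex_normals, to_other)
    keep = np.nonzero(facing <= exclude_cos)[0]
    if len(keep) < 4:
        keep = np.arange(len(pts))
    n_keep = max(4, int(np.ceil(fraction * len(keep))))
    sel = keep[farthest_point_subsample(pts[keep], n_keep, seed=seed)]
    src = pts[sel]
    return src, transform.apply(src)


def preliminary_morph(capsule: TriMesh, bone_landmarks_reduced,
                      segmentation: Optional[CapsuleSegmentation] = None,
                      proximal_transform=None,
                      distal_transform=None) -> TriMesh:
    """TPS-morph the capsule from the reduced bone landmarks.

    When a segmentation and the bone rigid transforms are supplied, the
    proximal / distal nodes are overwritten with their exact rigid images
    (they are attached to the bones).
    """
    src, tgt = bone_landmarks_reduced
    tps = fit_tps(np.asarray(src, float), np.asarray(tgt, float))
    verts = apply_tps(tps, capsule.vertices)
    if segmentation is not None:
        if proximal_transform is not None:
            idx = segmentation.proximal_nodes
            verts[idx] = proximal_transform.apply(capsule.vertices[idx])
        if distal_transform is not None:
            idx = segmentation.distal_nodes
            verts[idx] = distal_transform.apply(capsule.vertices[idx])
    return capsule.with_vertices(verts)


def detect_penetrations(bone: TriMesh, capsule: TriMesh,
                        baseline_signs: Optional[np.ndarray] = None,
                        tol: float = 1e-6) -> PenetrationReport:
    """Signed distances of bone nodes to the capsule surface.

    The capsule bounds the flesh around the joint, so its outward normals
    face the joint interior: a bone node that crossed onto the flesh side
    of the surface has negative signed distance.  Nodes with signed
    distance < -tol are penetrating.  When
    ``baseline_signs`` (pre-morph signed distances or their signs) is given,
    only nodes that experienced an orientation flip — previously outside,
    now inside — are reported.
    """
    sd, cp, fi = signed_distance(capsule, bone.vertices)
    mask = sd < -tol
    if baseline_signs is not None:
        base = np.asarray(baseline_signs, float)
        mask &= base > 0
    idx = np.nonzero(mask)[0]
    return PenetrationReport(
        penetrating_nodes=idx,
        signed_depths=sd[idx],
        nearest_faces=fi[idx],
        bone=bone,
    )


def resolve_penetrations(capsule: TriMesh, report: PenetrationReport,
                         max_iter: int = 50, clearance: float = 0.1,
                         fixed: Optional[Sequence[int]] = None) -> TriMesh:
    """Pull penetrated capsule patches outward until penetration-free.

    A penetrating bone node sits on the negative (anti-normal) side of its
    nearest capsule patch, so the patch is displaced by (depth + clearance)
    along the anti-normal direction — outward through and past the bone
    node — with a raised-cosine falloff (weight 0.5) over the 1-ring;
    per-vertex displacements take the max over penetrating nodes.
    Re-detects and iterates; raises PenetrationError with the residual
    report when ``max_iter`` is exhausted.
    """
    if report.is_empty:
        return capsule
    if report.bone is None:
        raise ValidationError("report carries no bone mesh to re-detect against")
    fixed_mask = np.zeros(capsule.n_vertices, dtype=bool)
    if fixed is not None:
        fixed_mask[np.asarray(list(fixed), dtype=np.int64)] = True

    current = capsule
    rep = report
    for _ in range(max_iter):
        if rep.is_empty:
            return current
        verts = current.vertices.copy()
        vn = current.vertex_normals
        disp = np.zeros(current.n_vertices)
        # vertex adjacency for the 1-ring falloff
        for node, depth, fi in zip(rep.penetrating_nodes, rep.signed_depths,
                                   rep.nearest_faces):
            pull = -float(depth) + clearance
            core = current.faces[fi]
            ring: set = set()
            for v in core:
                for nf in current.vertex_faces[v]:
                    ring.update(current.faces[nf].tolist())
            ring -= set(core.tolist())
            for v in core:
                disp[v] = max(disp[v], pull)
            for v in ring:
                disp[v] = max(disp[v], 0.5 * pull)  # cos^2(pi/4) falloff
        disp[fixed_mask] = 0.0
        verts -= disp[:, None] * vn  # anti-normal: away from the bone side
        current = current.with_vertices(verts)
        rep = detect_penetrations(rep.bone, current)
    if not rep.is_empty:
        raise PenetrationError(
            f"{len(rep)} penetrations remain after {max_iter} iterations",
            report=rep,
        )
    return current


# ----------------------------------------------------------------------
# Interface refinement
# ----------------------------------------------------------------------

def chamfer_distance(a: TriMesh, b: TriMesh) -> float:
    """Symmetric mean nearest-point distance between the two meshes,
    point-sampled at nodes plus face centroids."""
    pa = np.vstack([a.vertices, a.face_centroids])
    pb = np.vstack([b.vertices, b.face_centroids])
    da = cKDTree(pb).query(pa)[0]
    db = cKDTree(pa).query(pb)[0]
    return 0.5 * (float(da.mean()) + float(db.mean()))


def edge_length_cv(mesh: TriMesh) -> float:
    """Coefficient of variation of edge lengths."""
    e = mesh.edges
    lens = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]],
                          axis=1)
    return float(lens.std() / lens.mean())


def _face_pairs(mesh: TriMesh) -> np.ndarray:
    pairs = [fl for fl in mesh.edge_faces.values() if len(fl) == 2]
    return np.asarray(pairs, dtype=np.int64) if pairs else np.empty((0, 2), np.int64)


class _RefineLoss:
    """Loss L = w_c Chamfer^2 + w_e Var(edge)/mean^2 + w_n mean(1 - cos)
    with analytic gradients (Chamfer correspondences frozen per evaluation).
    """

    def __init__(self, topology: TriMesh, reference: TriMesh,
                 w_c: float, w_e: float, w_n: float):
        self.faces = topology.faces
        self.edges = topology.edges
        self.pairs = _face_pairs(topology)
        self.w_c, self.w_e, self.w_n = w_c, w_e, w_n
        ref_samples = np.vstack([reference.vertices, reference.face_centroids])
        self.ref_samples = ref_samples
        self.ref_tree = cKDTree(ref_samples)

    def _samples(self, verts):
        cent = verts[self.faces].mean(axis=1)
        return np.vstack([verts, cent])

    def __call__(self, verts: np.ndarray):
        n_v = len(verts)
        grad = np.zeros_like(verts)

        # --- Chamfer (squared, symmetric) -----------------------------
        samples = self._samples(verts)
        d_ab, j_ab = self.ref_tree.query(samples)
        diff_ab = samples - self.ref_samples[j_ab]
        tree_cur = cKDTree(samples)
        d_ba, j_ba = tree_cur.query(self.ref_samples)
        loss_c = float((d_ab**2).mean() + (d_ba**2).mean())
        g_samples = 2.0 * diff_ab / len(samples)
        np.add.at(
            g_samples, j_ba,
            2.0 * (samples[j_ba] - self.ref_samples) / len(self.ref_samples),
        )
        grad_c = g_samples[:n_v].copy()
        cent_g = g_samples[n_v:] / 3.0
        for k in range(3):
            np.add.at(grad_c, self.faces[:, k], cent_g)
        grad += self.w_c * grad_c

        # --- edge-length consistency ----------------------------------
        ev = verts[self.edges[:, 0]] - verts[self.edges[:, 1]]
        L = np.linalg.norm(ev, axis=1)
        mean = L.mean()
        var = L.var()
        loss_e = float(var / mean**2)
        n_e = len(L)
        dA = 2.0 * (L - mean) / n_e
        dB = 2.0 * mean / n_e
        dE_dL = (dA * mean**2 - var * dB) / mean**4
        gL = (dE_dL / np.maximum(L, 1e-12))[:, None] * ev
        grad_e = np.zeros_like(verts)
        np.add.at(grad_e, self.edges[:, 0], gL)
        np.add.at(grad_e, self.edges[:, 1], -gL)
        grad += self.w_e * grad_e

        # --- normal coherence -----------------------------------------
        tri = verts[self.faces]
        c = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        clen = np.linalg.norm(c, axis=1)
        clen_safe = np.maximum(clen, 1e-12)
        nf = c / clen_safe[:, None]
        loss_n = 0.0
        if len(self.pairs):
            f, g = self.pairs[:, 0], self.pairs[:, 1]
            dots = np.einsum("ij,ij->i", nf[f], nf[g])
            n_p = len(self.pairs)
            loss_n = float((1.0 - dots).mean())
            grad_n = np.zeros_like(verts)
            for a_idx, b_idx in ((f, g), (g, f)):
                # gradient of -nf[a].nf[b] w.r.t. the vertices of face a
                a_vec = (nf[b_idx] - dots[:, None] * nf[a_idx]) / \
                    clen_safe[a_idx, None]
                coef = -1.0 / n_p
                fa = self.faces[a_idx]
                va = verts[fa]
                for k in range(3):
                    edge = va[:, (k + 1) % 3] - va[:, (k + 2) % 3]
                    np.add.at(grad_n, fa[:, k], coef * np.cross(edge, a_vec))
            grad += self.w_n * grad_n

        loss = self.w_c * loss_c + self.w_e * loss_e + self.w_n * loss_n
        return loss, grad


def refine_interface(capsule_raw: TriMesh, reference: TriMesh,
                     fixed: Optional[Sequence[int]] = None,
                     w_c: float = 1.0, w_e: float = 0.1, w_n: float = 0.01,
                     step: float = 0.05, decay: float = 0.95,
                     max_iter: int = 500, rel_tol: float = 1e-5) -> TriMesh:
    """Redistribute capsule nodes for mesh regularity.

    Gradient descent over the non-fixed node positions of
    w_c * Chamfer(current, reference)^2 + w_e * Var(edge)/mean^2 +
    w_n * mean(1 - cos angle between adjacent face normals).  ``reference``
    is the penetration-fixed surface (the shape target), so penetration
    freedom is preserved.  Steps are capped at ``step`` mm (decayed by
    ``decay`` every 50 iterations); a step that flips a face normal is
    rolled back and the solve halts with a warning.
    """
    if capsule_raw.faces.shape != reference.faces.shape or \
            np.any(capsule_raw.faces != reference.faces):
        raise ValidationError("capsule_raw and reference must share topology")
    fixed_mask = np.zeros(capsule_raw.n_vertices, dtype=bool)
    if fixed is not None and len(list(fixed)):
        fixed_mask[np.asarray(list(fixed), dtype=np.int64)] = True

    loss_fn = _RefineLoss(capsule_raw, reference, w_c, w_e, w_n)
    verts = capsule_raw.vertices.copy()
    base_normals = capsule_raw.face_normals.copy()
    loss, grad = loss_fn(verts)
    cur_step = step
    for it in range(1, max_iter + 1):
        grad[fixed_mask] = 0.0
        gmax = np.abs(grad).max()
        if gmax < 1e-15:
            break
        new_verts = verts - grad * (cur_step / gmax)
        tri = new_verts[capsule_raw.faces]
        c = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        areas = 0.5 * np.linalg.norm(c, axis=1)
        flipped = (areas < 1e-12) | (
            np.einsum("ij,ij->i", c, base_normals) < 0
        )
        if np.any(flipped):
            warnings.warn(
                f"refinement step {it} would flip {int(flipped.sum())} "
                "faces; rolled back and halted",
                RuntimeWarning,
            )
            break
        new_loss, new_grad = loss_fn(new_verts)
        if new_loss > loss:
            cur_step *= 0.5
            if cur_step < 1e-6:
                break
            continue
        rel = (loss - new_loss) / max(abs(loss), 1e-30)
        verts, loss, grad = new_verts, new_loss, new_grad
        if it % 50 == 0:
            cur_step *= decay
        if rel < rel_tol:
            break
    out = capsule_raw.with_vertices(verts)
    return out


def deform_soft_tissue(model: FEModel, boundary_landmarks, flesh_parts,
                       exact_targets: Optional[Dict[int, np.ndarray]] = None,
                       lam: float = 0.0) -> FEModel:
    """TPS-displace all nodes of ``flesh_parts`` from boundary landmarks.

    ``boundary_landmarks`` is a (source (n,3), target (n,3)) pair built from
    the refined capsule segments plus bone surface nodes.  Nodes listed in
    ``exact_targets`` (node id -> position) are set exactly afterwards.
    Returns a new model.
    """
    src, tgt = boundary_landmarks
    tps = fit_tps(np.asarray(src, float), np.asarray(tgt, float), lam=lam)
    out = model.copy()
    nids: set = set()
    for pid in flesh_parts:
        nids.update(out.part_node_ids(pid))
    nids = sorted(nids)
    if nids:
        out.set_coords(nids, apply_tps(tps, out.coords_of(nids)))
    if exact_targets:
        for nid, pos in exact_targets.items():
            out.nodes[int(nid)] = np.asarray(pos, float).copy()
    return out
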