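"""Closest-point and signed-distance queries against triangle meshes.

Sign convention: sign of dot(query - closest point, pseudonormal of the
nearest feature), with angle-weighted pseudonormals at vertices and
face-normal sums at edges — positive on the outward-normal side.  Works on
watertight and near-watertight meshes.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .surface import TriMesh

__all__ = ["closest_points", "signed_distance", "unsigned_distance"]


def _face_tree(mesh: TriMesh) -> cKDTree:
    if "face_tree" not in mesh._cache:
        mesh._cache["face_tree"] = cKDTree(mesh.face_centroids)
    return mesh._cache["face_tree"]


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle (Ericson's algorithm, vectorized).

    p: (..., 3) broadcastable to tri's leading shape; tri: (..., 3, 3).
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp_ = p - c
    d5 = np.einsum("...i,...i->...", ab, cp_)
    d6 = np.einsum("...i,...i->...", ac, cp_)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    denom_ab = np.where(d1 - d3 != 0, d1 - d3, 1.0)
    v_ab = np.clip(d1 / denom_ab, 0.0, 1.0)
    denom_ac = np.where(d2 - d6 != 0, d2 - d6, 1.0)
    w_ac = np.clip(d2 / denom_ac, 0.0, 1.0)
    denom_bc = np.where((d4 - d3) + (d5 - d6) != 0, (d4 - d3) + (d5 - d6), 1.0)
    w_bc = np.clip((d4 - d3) / denom_bc, 0.0, 1.0)

    denom = np.where(va + vb + vc != 0, va + vb + vc, 1.0)
    v_in = vb / denom
    w_in = vc / denom

    out = a + v_in[..., None] * ab + w_in[..., None] * ac  # interior default

    reg_bc = (d4 - d3 >= 0) | (d5 - d6 >= 0)
    cond_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(cond_bc[..., None], b + w_bc[..., None] * (c - b), out)
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(cond_ac[..., None], a + w_ac[..., None] * ac, out)
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(cond_ab[..., None], a + v_ab[..., None] * ab, out)
    cond_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(cond_c[..., None], c, out)
    cond_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(cond_b[..., None], b, out)
    cond_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(cond_a[..., None], a, out)
    return out


def closest_points(mesh: TriMesh, points: np.ndarray, k: int = 48):
    """Closest surface points.

    Returns (distances (n,), closest points (n, 3), face indices (n,)).
    Candidate faces are pruned with a k-d tree over face centroids.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if mesh.n_faces == 0:
        raise ValidationError("mesh has no faces")
    kn = min(k, mesh.n_faces)
    tree = _face_tree(mesh)
    _, idx = tree.query(pts, kn)
    idx = np.atleast_2d(idx)
    if idx.shape[0] != len(pts):
        idx = idx.reshape(len(pts), -1)
    tri = mesh.vertices[mesh.faces[idx]]  # (n, kn, 3, 3)
    cp = _closest_on_triangles(pts[:, None, :], tri)
    d2 = np.einsum("nkj,nkj->nk", cp - pts[:, None, :], cp - pts[:, None, :])
    j = np.argmin(d2, axis=1)
    rows = np.arange(len(pts))
    return (
        np.sqrt(d2[rows, j]),
        cp[rows, j],
        idx[rows, j],
    )


def unsigned_distance(mesh: TriMesh, points: np.ndarray, k: int = 48) -> np.ndarray:
    return closest_points(mesh, points, k=k)[0]


def _edge_pseudonormals(mesh: TriMesh):
    if "edge_pseudonormals" not in mesh._cache:
        fn = mesh.face_normals
        d = {}
        for edge, fl in mesh.edge_faces.items():
            n = fn[fl].sum(axis=0)
            ln = np.linalg.norm(n)
            d[edge] = n / ln if ln > 1e-12 else fn[fl[0]]
        mesh._cache["edge_pseudonormals"] = d
    return mesh._cache["edge_pseudonormals"]


def signed_distance(mesh: TriMesh, points: np.ndarray, k: int = 48):
    """Signed distances (positive outside) plus closest points and faces.

    Requires an orientable, consistently wound mesh.
    """
    if not mesh.winding_consistent():
        raise ValidationError("mesh winding is inconsistent (unorientable)")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dist, cp, fi = closest_points(mesh, pts, k=k)

    verts = mesh.vertices
    faces = mesh.faces
    fn = mesh.face_normals
    vn = mesh.vertex_normals
    edge_n = _edge_pseudonormals(mesh)

    tri = verts[faces[fi]]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    # barycentric coordinates of the closest point
    v0 = b - a
    v1 = c - a
    v2 = cp - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    u = 1.0 - v - w
    bary = np.stack([u, v, w], axis=1)

    scale = np.sqrt(np.maximum(d00, d11))
    tol = 1e-9 + 1e-7 * scale
    near_zero = bary < tol[:, None]
    nz = near_zero.sum(axis=1)

    normals = fn[fi].copy()
    for i in np.nonzero(nz > 0)[0]:
        f = faces[fi[i]]
        if nz[i] == 1:
            # edge feature: the edge opposite the zero-weight corner
            kz = int(np.nonzero(near_zero[i])[0][0])
            e = (int(f[(kz + 1) % 3]), int(f[(kz + 2) % 3]))
            key = e if e[0] < e[1] else (e[1], e[0])
            normals[i] = edge_n.get(key, normals[i])
        else:
            # vertex feature: the corner with the dominant weight
            kv = int(np.argmax(bary[i]))
            normals[i] = vn[f[kv]]

    side = np.einsum("ij,ij->i", pts - cp, normals)
    sign = np.where(side >= 0, 1.0, -1.0)
    return sign * dist, cp, fi
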