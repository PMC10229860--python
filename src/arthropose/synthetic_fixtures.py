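"""Analytic fixtures with known ground truth.

Sphere / cylinder / ellipsoid knee geometries, a tube capsule around two
bone cylinders, a small spine column, and a toy limb FE model.  Vertices are
placed exactly on the analytic surfaces (no post-smoothing) so curvature
oracles are clean; every fixture is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional

import numpy as np

from .errors import ValidationError
from .fe_model_io import FEModel
from .geometry_core import PlateauPlane, curvature_tensor_field
from .knee_trajectory import KneeGeometry
from .surface import TriMesh

__all__ = [
    "FixtureSpec",
    "KneeFixture",
    "TubeCapsuleFixture",
    "ToyLimbFixture",
    "make_sphere_knee",
    "make_cylinder_knee",
    "make_ellipsoid_knee",
    "make_tube_capsule",
    "make_spine_column",
    "make_toy_limb",
]


@dataclass
class FixtureSpec:
    kind: str = "toy_limb"
    radius: float = 20.0
    gap: float = 0.0
    length: float = 40.0
    edge: float = 1.0
    seed: int = 0
    params: Dict = dc_field(default_factory=dict)

    def validate(self) -> None:
        if self.radius <= 0 or self.length <= 0 or self.edge <= 0:
            raise ValidationError("fixture dimensions must be positive")
        if self.edge >= self.radius / 4:
            raise ValidationError("mesh edge length must be < smallest radius / 4")


@dataclass
class KneeFixture:
    geometry: KneeGeometry
    truth: Dict


@dataclass
class TubeCapsuleFixture:
    capsule: TriMesh
    femur: TriMesh
    tibia: TriMesh
    truth: Dict


@dataclass
class ToyLimbFixture:
    model: FEModel
    config: Dict
    truth: Dict


# ----------------------------------------------------------------------
# Parametric surface meshes
# ----------------------------------------------------------------------

def _ellipsoid_mesh(center, abc, edge: float) -> TriMesh:
    """Watertight lat-long ellipsoid with exact vertices and poles on ±z."""
    a, b, c = abc
    cx, cy, cz = center
    rmax = max(a, b, c)
    nlat = max(8, int(np.ceil(np.pi * rmax / edge)))
    nlon = max(12, int(np.ceil(2 * np.pi * rmax / edge)))
    verts = [(cx, cy, cz + c)]  # north pole
    rows = []
    for i in range(1, nlat):
        th = np.pi * i / nlat
        row = []
        for j in range(nlon):
            ph = 2 * np.pi * j / nlon
            row.append(len(verts))
            verts.append(
                (
                    cx + a * np.sin(th) * np.cos(ph),
                    cy + b * np.sin(th) * np.sin(ph),
                    cz + c * np.cos(th),
                )
            )
        rows.append(row)
    south = len(verts)
    verts.append((cx, cy, cz - c))

    faces = []
    for j in range(nlon):
        faces.append([0, rows[0][j], rows[0][(j + 1) % nlon]])
    for i in range(len(rows) - 1):
        r0, r1 = rows[i], rows[i + 1]
        for j in range(nlon):
            j1 = (j + 1) % nlon
            faces.append([r0[j], r1[j], r1[j1]])
            faces.append([r0[j], r1[j1], r0[j1]])
    for j in range(nlon):
        faces.append([south, rows[-1][(j + 1) % nlon], rows[-1][j]])
    return TriMesh(np.asarray(verts, float), np.asarray(faces, np.int64))


def _cylinder_strip(axis_point, R: float, length: float, edge: float,
                    phi_max_deg: float = 110.0) -> TriMesh:
    """Open strip of a cylinder with axis parallel to y through
    ``axis_point``; phi = 0 points to -z (the lowest generatrix)."""
    px, py, pz = axis_point
    phim = np.radians(phi_max_deg)
    nphi = max(8, int(np.ceil(2 * phim * R / edge)))
    ny = max(4, int(np.ceil(length / edge)))
    phis = np.linspace(-phim, phim, nphi + 1)
    ys = np.linspace(py - length / 2, py + length / 2, ny + 1)
    verts = []
    for y in ys:
        for ph in phis:
            verts.append((px + R * np.sin(ph), y, pz - R * np.cos(ph)))
    faces = []
    ncol = nphi + 1
    for j in range(ny):
        for i in range(nphi):
            A = j * ncol + i
            B = j * ncol + i + 1
            C = (j + 1) * ncol + i + 1
            D = (j + 1) * ncol + i
            faces.append([A, B, C])
            faces.append([A, C, D])
    mesh = TriMesh(np.asarray(verts, float), np.asarray(faces, np.int64))
    # orient outward (away from the axis)
    mid = mesh.face_centroids - np.array([px, 0.0, pz])
    mid[:, 1] = 0.0
    if np.einsum("ij,ij->i", mesh.face_normals, mid).mean() < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def _revolve(profile, nseg: int = 32, close: bool = False,
             stagger: bool = False) -> TriMesh:
    """Surface of revolution about the z axis.

    ``profile`` is a list of (r, z); points with r == 0 become single pole
    vertices (triangle fans).  ``close=True`` connects last profile point
    back to the first (closed tube).  ``stagger=True`` offsets every other
    ring by half an angular step (near-equilateral triangulation; use an
    even ring count with ``close``).
    """
    verts: List = []
    ring_index: List = []
    for idx, (r, z) in enumerate(profile):
        if r <= 1e-12:
            ring_index.append((len(verts), True))
            verts.append((0.0, 0.0, z))
        else:
            start = len(verts)
            off = (np.pi / nseg) * (idx % 2) if stagger else 0.0
            for j in range(nseg):
                ph = 2 * np.pi * j / nseg + off
                verts.append((r * np.cos(ph), r * np.sin(ph), z))
            ring_index.append((start, False))
    faces = []
    n = len(profile)
    pairs = [(k, k + 1) for k in range(n - 1)]
    if close:
        pairs.append((n - 1, 0))
    for k0, k1 in pairs:
        (s0, pole0), (s1, pole1) = ring_index[k0], ring_index[k1]
        if pole0 and pole1:
            continue
        if pole0:
            for j in range(nseg):
                j1 = (j + 1) % nseg
                faces.append([s0, s1 + j, s1 + j1])
        elif pole1:
            for j in range(nseg):
                j1 = (j + 1) % nseg
                faces.append([s1, s0 + j1, s0 + j])
        else:
            # split direction follows the stagger so no edge spans more
            # than one angular step
            upper_shifted = stagger and (k1 % 2) > (k0 % 2)
            for j in range(nseg):
                j1 = (j + 1) % nseg
                if upper_shifted:
                    faces.append([s0 + j, s1 + j, s0 + j1])
                    faces.append([s0 + j1, s1 + j, s1 + j1])
                else:
                    faces.append([s0 + j, s1 + j, s1 + j1])
                    faces.append([s0 + j, s1 + j1, s0 + j1])
    mesh = TriMesh(np.asarray(verts, float), np.asarray(faces, np.int64))
    if mesh.is_watertight() and mesh.signed_volume() < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


# ----------------------------------------------------------------------
# Knee fixtures
# ----------------------------------------------------------------------

def _plateau_patch(center, half: float, z: float, n: int = 6) -> TriMesh:
    xs = np.linspace(center[0] - half, center[0] + half, n + 1)
    ys = np.linspace(center[1] - half, center[1] + half, n + 1)
    verts = [(x, y, z) for y in ys for x in xs]
    faces = []
    for j in range(n):
        for i in range(n):
            A = j * (n + 1) + i
            B = A + 1
            C = A + n + 2
            D = A + n + 1
            faces.append([A, B, C])
            faces.append([A, C, D])
    return TriMesh(np.asarray(verts, float), np.asarray(faces, np.int64))


def _assemble_knee(mesh_m, mesh_l, plateau_m, plateau_l, patches):
    field_m = curvature_tensor_field(mesh_m)
    field_l = curvature_tensor_field(mesh_l)
    field_m.compartment = "medial"
    field_l.compartment = "lateral"
    return KneeGeometry(
        condyle_medial=field_m,
        condyle_lateral=field_l,
        plateau_medial=plateau_m,
        plateau_lateral=plateau_l,
        tibia_bodies=patches,
    )


def make_sphere_knee(R: float = 20.0, gap: float = 0.0,
                     edge: float = 1.0) -> KneeFixture:
    """Two spherical condyles of radius R tangent to planar plateaus.

    Medial center (0, -2R, R - gap... ); plateaus at z = -gap with normal
    +z.  Analytic truth: osculating radius R in every direction, helical
    axis through the two centers (parallel to +y).
    """
    FixtureSpec(kind="sphere_knee", radius=R, gap=gap, edge=edge).validate()
    c_m = np.array([0.0, -2 * R, R])
    c_l = np.array([0.0, 2 * R, R])
    mesh_m = _ellipsoid_mesh(c_m, (R, R, R), edge)
    mesh_l = _ellipsoid_mesh(c_l, (R, R, R), edge)
    plateau_m = PlateauPlane([0.0, -2 * R, -gap], [0.0, 0.0, 1.0])
    plateau_l = PlateauPlane([0.0, 2 * R, -gap], [0.0, 0.0, 1.0])
    patches = [
        _plateau_patch(c_m[:2], 1.5 * R, -gap),
        _plateau_patch(c_l[:2], 1.5 * R, -gap),
    ]
    geom = _assemble_knee(mesh_m, mesh_l, plateau_m, plateau_l, patches)
    truth = {
        "r_m": R, "r_l": R,
        "center_medial": c_m, "center_lateral": c_l,
        "axis_direction": np.array([0.0, 1.0, 0.0]),
        "kappa": 1.0 / R,
    }
    return KneeFixture(geom, truth)


def make_cylinder_knee(R: float = 20.0, length: float = 40.0,
                       edge: float = 1.0) -> KneeFixture:
    """Two coaxial cylindrical condyle strips (axis parallel +y at height
    z = R) over planar plateaus at z = 0.  Truth: fixed helical axis =
    the cylinder axis; circumferential curvature 1/R, axial 0."""
    FixtureSpec(kind="cylinder_knee", radius=R, length=length,
                edge=edge).validate()
    axis_m = np.array([0.0, -2 * R, R])
    axis_l = np.array([0.0, 2 * R, R])
    mesh_m = _cylinder_strip(axis_m, R, length, edge)
    mesh_l = _cylinder_strip(axis_l, R, length, edge)
    plateau_m = PlateauPlane([0.0, -2 * R, 0.0], [0.0, 0.0, 1.0])
    plateau_l = PlateauPlane([0.0, 2 * R, 0.0], [0.0, 0.0, 1.0])
    patches = [
        _plateau_patch(axis_m[:2], 1.5 * R, 0.0),
        _plateau_patch(axis_l[:2], 1.5 * R, 0.0),
    ]
    geom = _assemble_knee(mesh_m, mesh_l, plateau_m, plateau_l, patches)
    truth = {
        "r_m": R, "r_l": R,
        "axis_direction": np.array([0.0, 1.0, 0.0]),
        "axis_point": np.array([0.0, 0.0, R]),
        "kappa_circumferential": 1.0 / R,
        "kappa_axial": 0.0,
    }
    return KneeFixture(geom, truth)


def make_ellipsoid_knee(a: float = 24.0, b: float = 20.0, c: float = 16.0,
                        edge: float = 1.0,
                        abc_lateral=None) -> KneeFixture:
    """Ellipsoidal condyles (semi-axes a, b, c along x, y, z) tangent to
    plateaus at z = 0.  Truth: normal curvature at the bottom pole along
    the x tangent is c/a^2, along the y tangent c/b^2.  ``abc_lateral``
    (optional) gives the lateral compartment different semi-axes, which
    makes the per-step helical axis genuinely vary."""
    FixtureSpec(kind="ellipsoid_knee", radius=min(a, b, c),
                edge=edge).validate()
    al, bl, cl = abc_lateral if abc_lateral is not None else (a, b, c)
    sep = 2 * max(a, b, c, al, bl, cl)
    c_m = np.array([0.0, -sep, c])
    c_l = np.array([0.0, sep, cl])
    mesh_m = _ellipsoid_mesh(c_m, (a, b, c), edge)
    mesh_l = _ellipsoid_mesh(c_l, (al, bl, cl), edge)
    plateau_m = PlateauPlane([0.0, -sep, 0.0], [0.0, 0.0, 1.0])
    plateau_l = PlateauPlane([0.0, sep, 0.0], [0.0, 0.0, 1.0])
    patches = [
        _plateau_patch(c_m[:2], 1.5 * max(a, b), 0.0),
        _plateau_patch(c_l[:2], 1.5 * max(a, b), 0.0),
    ]
    geom = _assemble_knee(mesh_m, mesh_l, plateau_m, plateau_l, patches)
    truth = {
        "kappa_pole_x": c / a**2,
        "kappa_pole_y": c / b**2,
        "centers": (c_m, c_l),
    }
    return KneeFixture(geom, truth)


# ----------------------------------------------------------------------
# Tube capsule fixture (morph-contact oracle)
# ----------------------------------------------------------------------

def make_tube_capsule(bone_radius: float = 5.0, capsule_inner: float = 6.2,
                      capsule_outer: float = 8.5, half_gap: float = 1.0,
                      bone_length: float = 19.0, capsule_half_height: float = 8.0,
                      ring_radius: float = 5.4, nseg: int = 32) -> TubeCapsuleFixture:
    """A closed revolved capsule around two coaxial bone cylinders.

    The bones are capped cylinders along z separated by ``2 * half_gap`` at
    mid-section.  The capsule's end rings (radius ``ring_radius``) sit
    within classification tolerance of the bone lateral surfaces; the inner
    wall faces the bones (keep its clearance above the segmentation
    tolerance or it gets classified as attached), the outer wall faces
    away.  Staggered rings give a near-uniform edge-length baseline.
    """
    femur = _revolve(
        [(0.0, half_gap), (bone_radius, half_gap),
         (bone_radius, half_gap + bone_length), (0.0, half_gap + bone_length)],
        nseg=nseg,
    )
    tibia = _revolve(
        [(0.0, -half_gap - bone_length), (bone_radius, -half_gap - bone_length),
         (bone_radius, -half_gap), (0.0, -half_gap)],
        nseg=nseg,
    )
    h = capsule_half_height
    taper = 1.5  # inner wall pulls in to the ring radius at the ends
    target_edge = 2 * np.pi * (capsule_inner + capsule_outer) / 2 / nseg
    corners = [
        (ring_radius, h), (capsule_outer, h), (capsule_outer, -h),
        (ring_radius, -h), (capsule_inner, -h + taper),
        (capsule_inner, h - taper),
    ]
    # profile spacing sqrt(3)/2 of the circumferential step + staggered
    # rings gives a near-equilateral triangulation (uniform edge lengths)
    target_edge *= np.sqrt(3) / 2
    prof = []
    for k in range(len(corners)):
        p0 = np.asarray(corners[k], float)
        p1 = np.asarray(corners[(k + 1) % len(corners)], float)
        nsub = max(1, int(round(np.linalg.norm(p1 - p0) / target_edge)))
        for t in np.linspace(0, 1, nsub, endpoint=False):
            prof.append(tuple(p0 + t * (p1 - p0)))
    if len(prof) % 2:  # staggered closed tube needs an even ring count
        prof.append(tuple((np.asarray(prof[-1]) + np.asarray(corners[0])) / 2))
    capsule = _revolve(prof, nseg=nseg, close=True, stagger=True)
    truth = {
        "ring_radius": ring_radius,
        "inner_radius": capsule_inner,
        "outer_radius": capsule_outer,
        "half_height": h,
    }
    return TubeCapsuleFixture(capsule=capsule, femur=femur, tibia=tibia,
                              truth=truth)


# ----------------------------------------------------------------------
# Hex building blocks for the toy limb
# ----------------------------------------------------------------------

def _spherify(p: np.ndarray) -> np.ndarray:
    """Smooth cube-to-sphere map; cube surface points land exactly on the
    unit sphere."""
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    sx = x * np.sqrt(np.maximum(1 - y**2 / 2 - z**2 / 2 + y**2 * z**2 / 3, 0))
    sy = y * np.sqrt(np.maximum(1 - z**2 / 2 - x**2 / 2 + z**2 * x**2 / 3, 0))
    sz = z * np.sqrt(np.maximum(1 - x**2 / 2 - y**2 / 2 + x**2 * y**2 / 3, 0))
    return np.stack([sx, sy, sz], axis=-1)


def _fix_orientation(pts: np.ndarray) -> np.ndarray:
    """Flip the k axis of a structured grid if its hexes are inverted."""
    d_i = pts[1, 0, 0] - pts[0, 0, 0]
    d_j = pts[0, 1, 0] - pts[0, 0, 0]
    d_k = pts[0, 0, 1] - pts[0, 0, 0]
    if np.linalg.det(np.stack([d_i, d_j, d_k])) < 0:
        return pts[:, :, ::-1]
    return pts


def _ogrid_disc_blocks(radius: float, n_core: int = 2, nr: int = 2,
                       core_frac: float = 0.5):
    """2D O-grid disc: square core + 4 blended ring blocks.

    Returns a list of (ni, nj, 2) point grids whose seams coincide exactly.
    """
    a = core_frac * radius
    u = np.linspace(-1.0, 1.0, n_core + 1)
    core = np.stack(np.meshgrid(a * u, a * u, indexing="ij"), axis=-1)
    blocks = [core]
    # sides: +x, +y, -x, -y with matching corner angles
    angles0 = (-np.pi / 4, np.pi / 4, 3 * np.pi / 4, 5 * np.pi / 4)
    for side, th0 in enumerate(angles0):
        t = np.linspace(0.0, 1.0, n_core + 1)
        th = th0 + t * (np.pi / 2)
        circ = radius * np.stack([np.cos(th), np.sin(th)], axis=-1)
        if side == 0:
            sq = np.stack([np.full_like(t, a), a * (2 * t - 1)], axis=-1)
        elif side == 1:
            sq = np.stack([a * (1 - 2 * t), np.full_like(t, a)], axis=-1)
        elif side == 2:
            sq = np.stack([np.full_like(t, -a), a * (1 - 2 * t)], axis=-1)
        else:
            sq = np.stack([a * (2 * t - 1), np.full_like(t, -a)], axis=-1)
        s = np.linspace(0.0, 1.0, nr + 1)
        block = (1 - s[None, :, None]) * sq[:, None, :] + \
            s[None, :, None] * circ[:, None, :]
        blocks.append(block)
    return blocks


def _add_ogrid_cylinder(builder, pid: int, radius: float, zs: np.ndarray,
                        n_core: int = 2, nr: int = 2):
    """All-hex cylinder along z via a 2D O-grid section; returns the node-id
    arrays of all blocks (core first)."""
    out = []
    for sec in _ogrid_disc_blocks(radius, n_core=n_core, nr=nr):
        ni, nj = sec.shape[:2]
        pts = np.empty((ni, nj, len(zs), 3))
        pts[..., :2] = sec[:, :, None, :]
        pts[..., 2] = zs[None, None, :]
        out.append(builder.add_grid_hexes(pid, _fix_orientation(pts)))
    return out


def _add_ogrid_ball(builder, pid: int, radius: float, center,
                    n_core: int = 2, nr: int = 2, core_frac: float = 0.5):
    """All-hex ball: cube core + 6 shell blocks blended onto the spherified
    cube surface (surface nodes lie exactly on the sphere)."""
    center = np.asarray(center, float)
    a = core_frac * radius
    u = np.linspace(-1.0, 1.0, n_core + 1)
    X, Y, Z = np.meshgrid(u, u, u, indexing="ij")
    core = np.stack([a * X, a * Y, a * Z], axis=-1)
    ids = [builder.add_grid_hexes(pid, _fix_orientation(core + center))]
    faces = (
        (0, 1.0), (0, -1.0), (1, 1.0), (1, -1.0), (2, 1.0), (2, -1.0),
    )
    s = np.linspace(0.0, 1.0, nr + 1)
    for axisn, sgn in faces:
        UU, VV = np.meshgrid(u, u, indexing="ij")
        cube_pt = np.zeros(UU.shape + (3,))
        other = [k for k in range(3) if k != axisn]
        cube_pt[..., other[0]] = UU
        cube_pt[..., other[1]] = VV
        cube_pt[..., axisn] = sgn
        inner = a * cube_pt
        outer = radius * _spherify(cube_pt)
        block = (1 - s[None, None, :, None]) * inner[:, :, None, :] + \
            s[None, None, :, None] * outer[:, :, None, :]
        ids.append(builder.add_grid_hexes(pid,
                                          _fix_orientation(block + center)))
    return ids


class _ModelBuilder:
    """Incremental FEModel builder with coordinate-keyed node dedup."""

    def __init__(self):
        self.model = FEModel()
        self._next_node = 1
        self._next_elem = 1
        self._coord_index: Dict = {}

    def node(self, xyz, merge: bool = True) -> int:
        key = tuple(np.round(np.asarray(xyz, float), 9))
        if merge and key in self._coord_index:
            return self._coord_index[key]
        nid = self._next_node
        self._next_node += 1
        self.model.nodes[nid] = np.asarray(xyz, float).copy()
        if merge:
            self._coord_index[key] = nid
        return nid

    def solid(self, pid: int, conn) -> int:
        eid = self._next_elem
        self._next_elem += 1
        self.model.solids[eid] = (pid, tuple(int(c) for c in conn))
        return eid

    def shell(self, pid: int, conn) -> int:
        eid = self._next_elem
        self._next_elem += 1
        self.model.shells[eid] = (pid, tuple(int(c) for c in conn))
        return eid

    def add_grid_hexes(self, pid: int, pts: np.ndarray, merge: bool = True):
        """pts: (ni, nj, nk, 3) structured grid -> hex elements.

        Returns the (ni, nj, nk) node-id array."""
        ni, nj, nk = pts.shape[:3]
        ids = np.empty((ni, nj, nk), dtype=np.int64)
        for i in range(ni):
            for j in range(nj):
                for k in range(nk):
                    ids[i, j, k] = self.node(pts[i, j, k], merge=merge)
        for i in range(ni - 1):
            for j in range(nj - 1):
                for k in range(nk - 1):
                    self.solid(pid, (
                        ids[i, j, k], ids[i + 1, j, k],
                        ids[i + 1, j + 1, k], ids[i, j + 1, k],
                        ids[i, j, k + 1], ids[i + 1, j, k + 1],
                        ids[i + 1, j + 1, k + 1], ids[i, j + 1, k + 1],
                    ))
        return ids


def make_spine_column(n_vertebrae: int = 5, size: float = 20.0,
                      height: float = 8.0, disc: float = 2.0,
                      part_start: int = 100) -> ToyLimbFixture:
    """Stacked box vertebrae along z with top/bottom node sets per segment."""
    b = _ModelBuilder()
    config: Dict = {"vertebrae": []}
    truth_centers = []
    z0 = 0.0
    xs = np.linspace(-size / 2, size / 2, 3)
    set_id = 1
    for v in range(n_vertebrae):
        pid = part_start + v
        b.model.parts[pid] = f"vertebra_{v + 1}"
        zs = np.linspace(z0, z0 + height, 3)
        pts = np.empty((3, 3, 3, 3))
        for i, x in enumerate(xs):
            for j, y in enumerate(xs):
                for k, z in enumerate(zs):
                    pts[i, j, k] = (x, y, z)
        ids = b.add_grid_hexes(pid, pts, merge=False)
        bottom = [int(i) for i in ids[:, :, 0].ravel()]
        top = [int(i) for i in ids[:, :, -1].ravel()]
        b.model.node_sets[set_id] = bottom
        b.model.node_sets[set_id + 1] = top
        config["vertebrae"].append(
            {"part": pid, "bottom_set": set_id, "top_set": set_id + 1}
        )
        set_id += 2
        truth_centers.append(np.array([0.0, 0.0, z0 + height / 2]))
        z0 += height + disc
    return ToyLimbFixture(model=b.model, config=config,
                          truth={"centers": truth_centers})


def make_toy_limb(spec: Optional[FixtureSpec] = None) -> ToyLimbFixture:
    """A toy lower limb: femur (shaft + two spherical condyle lobes + head),
    tibia, a quad-shell capsule tube bridging them, a hex flesh block, and
    an outer skin shell.

    The condyle lobes and head are spherified-cube hex balls sharing the
    femur part id with the shaft without node merging (overlapping solids;
    a fixture shortcut — bones only ever move rigidly and no solver is
    run).  Surface nodes of the lobes lie exactly on their spheres, so the
    knee/ball joint fits recover the generator truth.

    Returns the model, a joint-config dict, and the ground-truth record.
    """
    if spec is None:
        spec = FixtureSpec(kind="toy_limb")
    rng = np.random.default_rng(spec.seed)  # reserved; construction is exact
    del rng

    P_FEMUR, P_TIBIA, P_CAPSULE, P_FLESH, P_SKIN = 1, 2, 3, 4, 5
    b = _ModelBuilder()
    b.model.parts.update({
        P_FEMUR: "femur", P_TIBIA: "tibia", P_CAPSULE: "knee_capsule",
        P_FLESH: "flesh", P_SKIN: "skin",
    })

    lobe_R = 6.0
    lobe_centers = (np.array([0.0, -5.0, 6.0]), np.array([0.0, 5.0, 6.0]))
    head_R = 6.0
    head_center = np.array([0.0, 0.0, 60.0])
    femur_r, tibia_r = 5.5, 7.0
    femur_z = (9.0, 60.0)
    tibia_z = (-60.0, 0.0)

    # femur shaft (O-grid section)
    zs = np.linspace(femur_z[0], femur_z[1], 25)
    _add_ogrid_cylinder(b, P_FEMUR, femur_r, zs, n_core=3, nr=2)

    for c in lobe_centers:
        _add_ogrid_ball(b, P_FEMUR, lobe_R, c, n_core=3, nr=2,
                        core_frac=0.35)
    _add_ogrid_ball(b, P_FEMUR, head_R, head_center, n_core=3, nr=2,
                    core_frac=0.35)

    # tibia shaft
    zs = np.linspace(tibia_z[0], tibia_z[1], 26)
    _add_ogrid_cylinder(b, P_TIBIA, tibia_r, zs, n_core=3, nr=2)

    # capsule: revolved quad shells around z
    profile = [
        (6.3, 18.0),
        (12.0, 14.0), (14.0, 5.0), (14.0, -6.0), (11.0, -13.0),
        (7.8, -16.0),
        (8.5, -11.0), (10.0, -4.0), (12.5, 2.0), (12.5, 10.0), (9.0, 15.0),
    ]
    nseg = 16
    ring_ids = []
    for (r, z) in profile:
        ring = []
        for j in range(nseg):
            ph = 2 * np.pi * j / nseg
            ring.append(b.node((r * np.cos(ph), r * np.sin(ph), z), merge=False))
        ring_ids.append(ring)
    npro = len(profile)
    for k in range(npro):
        k1 = (k + 1) % npro
        for j in range(nseg):
            j1 = (j + 1) % nseg
            # wound so the extracted closed surface has positive volume
            b.shell(P_CAPSULE, (
                ring_ids[k][j], ring_ids[k1][j],
                ring_ids[k1][j1], ring_ids[k][j1],
            ))

    # flesh: hex box grid minus cells inside bones or the capsule volume
    cell = 5.0
    fx = np.arange(-17.5, 17.5 + 1e-9, cell)
    fz = np.arange(-57.5, 57.5 + 1e-9, cell)

    def inside_bone(p) -> bool:
        x, y, z = p
        rho2 = x * x + y * y
        margin = 1.2
        if femur_z[0] - margin < z < femur_z[1] + margin and \
                rho2 < (femur_r + margin) ** 2:
            return True
        if tibia_z[0] - margin < z < tibia_z[1] + margin and \
                rho2 < (tibia_r + margin) ** 2:
            return True
        for c in (*lobe_centers, head_center):
            if np.sum((p - c) ** 2) < (lobe_R + margin) ** 2:
                return True
        return False

    # flesh exclusion region: the whole capsule interior (joint space +
    # shell) dilated by ~1 mm so no flesh cell hugs the sliding interface.
    # Built from the profile with the inner wall collapsed onto the axis
    # and the rest pushed outward by the margin.
    margin = 1.2
    inner_wall = {5, 6, 7, 8, 9, 10}  # profile indices of the inner wall leg
    poly = []
    for k, (r, z) in enumerate(profile):
        if k in inner_wall:
            poly.append((0.0, z))
        else:
            poly.append((r + margin, z + (margin if z > 0 else -margin)))
    poly = np.asarray(poly)

    def inside_capsule(p) -> bool:
        rho = float(np.hypot(p[0], p[1]))
        z = float(p[2])
        # point-in-polygon in the (rho, z) half-plane
        inside = False
        for k in range(npro):
            r1, z1 = poly[k]
            r2, z2 = poly[(k + 1) % npro]
            if (z1 > z) != (z2 > z):
                xint = r1 + (z - z1) / (z2 - z1) * (r2 - r1)
                if rho < xint:
                    inside = not inside
        return inside

    node_grid: Dict = {}

    def flesh_node(i, j, k) -> int:
        key = (i, j, k)
        if key not in node_grid:
            node_grid[key] = b.node((fx[i], fx[j], fz[k]))
        return node_grid[key]

    flesh_cells = []
    for i in range(len(fx) - 1):
        for j in range(len(fx) - 1):
            for k in range(len(fz) - 1):
                centroid = np.array([
                    (fx[i] + fx[i + 1]) / 2,
                    (fx[j] + fx[j + 1]) / 2,
                    (fz[k] + fz[k + 1]) / 2,
                ])
                if inside_bone(centroid) or inside_capsule(centroid):
                    continue
                conn = (
                    flesh_node(i, j, k), flesh_node(i + 1, j, k),
                    flesh_node(i + 1, j + 1, k), flesh_node(i, j + 1, k),
                    flesh_node(i, j, k + 1), flesh_node(i + 1, j, k + 1),
                    flesh_node(i + 1, j + 1, k + 1), flesh_node(i, j + 1, k + 1),
                )
                b.solid(P_FLESH, conn)
                flesh_cells.append((i, j, k))

    # skin: boundary quads of the flesh complex, as shells
    cells = set(flesh_cells)
    face_dirs = (
        ((0, 0, -1), ((0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 0, 0))),
        ((0, 0, 1), ((0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1))),
        ((0, -1, 0), ((0, 0, 0), (1, 0, 0), (1, 0, 1), (0, 0, 1))),
        ((0, 1, 0), ((0, 1, 0), (0, 1, 1), (1, 1, 1), (1, 1, 0))),
        ((-1, 0, 0), ((0, 0, 0), (0, 0, 1), (0, 1, 1), (0, 1, 0))),
        ((1, 0, 0), ((1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 0, 1))),
    )
    for (i, j, k) in flesh_cells:
        for (di, dj, dk), corners in face_dirs:
            if (i + di, j + dj, k + dk) in cells:
                continue
            # only exterior-facing boundary: skip faces adjacent to excluded
            # interior cells unless they are on the outer box hull
            on_hull = (
                (di == -1 and i == 0) or (di == 1 and i == len(fx) - 2)
                or (dj == -1 and j == 0) or (dj == 1 and j == len(fx) - 2)
                or (dk == -1 and k == 0) or (dk == 1 and k == len(fz) - 2)
            )
            if not on_hull:
                continue
            conn = tuple(
                flesh_node(i + ci, j + cj, k + ck) for ci, cj, ck in corners
            )
            b.shell(P_SKIN, conn)

    # node sets for the joint config
    model = b.model

    def sphere_surface_nodes(part, center, R, pred=None):
        out = []
        for nid in model.part_node_ids(part):
            p = model.nodes[nid]
            if abs(np.linalg.norm(p - center) - R) < 1e-6:
                if pred is None or pred(p):
                    out.append(nid)
        return out

    SET_CM, SET_CL, SET_PM, SET_PL, SET_HEAD = 11, 12, 13, 14, 15
    cm = sphere_surface_nodes(P_FEMUR, lobe_centers[0], lobe_R,
                              lambda p: p[2] < lobe_centers[0][2] - 1e-9)
    cl = sphere_surface_nodes(P_FEMUR, lobe_centers[1], lobe_R,
                              lambda p: p[2] < lobe_centers[1][2] - 1e-9)
    top = [n for n in model.part_node_ids(P_TIBIA)
           if abs(model.nodes[n][2] - tibia_z[1]) < 1e-9]
    pm = [n for n in top if model.nodes[n][1] <= 0]
    pl = [n for n in top if model.nodes[n][1] >= 0]
    head = sphere_surface_nodes(P_FEMUR, head_center, head_R)
    model.node_sets.update({
        SET_CM: cm, SET_CL: cl, SET_PM: pm, SET_PL: pl, SET_HEAD: head,
    })

    config = {
        "root_parts": [P_FEMUR],
        "joints": {
            "hip": {
                "type": "ball",
                "surface_set": SET_HEAD,
                "driven_parts": [P_FEMUR],
                "child_joints": ["knee"],
            },
            "knee": {
                "type": "knee",
                "condyle_medial_set": SET_CM,
                "condyle_lateral_set": SET_CL,
                "plateau_medial_set": SET_PM,
                "plateau_lateral_set": SET_PL,
                "condyle_part": P_FEMUR,
                "driven_parts": [P_TIBIA],
                "child_joints": [],
                "capsule_part": P_CAPSULE,
                "flesh_parts": [P_FLESH, P_SKIN],
                "proximal_part": P_FEMUR,
                "distal_part": P_TIBIA,
            },
        },
    }
    truth = {
        "lobe_centers": lobe_centers,
        "lobe_radius": lobe_R,
        "head_center": head_center,
        "head_radius": head_R,
        "knee_axis_direction": np.array([0.0, 1.0, 0.0]),
        "part_ids": {
            "femur": P_FEMUR, "tibia": P_TIBIA, "capsule": P_CAPSULE,
            "flesh": P_FLESH, "skin": P_SKIN,
        },
    }
    model.validate()
    return ToyLimbFixture(model=model, config=config, truth=truth)
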