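"""Geometrically neutral tibiofemoral flexion trajectory.

Iterates contact search -> helical-axis optimization -> incremental rigid
rotation of the tibia side.  The helical axis passes through the two
intersection points I = p + r n (contact point deflected along the condyle
normal by the osculating radius r), with (r_m, r_l) solved by a fixed-point
scheme that realizes

    argmin (r_m - 1/(t_m^T C(p_m) t_m))^2 + (r_l - 1/(t_l^T C(p_l) t_l))^2

where each tangent t is perpendicular to the current axis candidate within
the contact tangent plane.  Condyles stay in their convex shape; tibial
plateaus are treated as planes.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np

from .errors import (
    ArthroposeError,
    DegenerateAxisError,
    NonConvergenceError,
    NonPositiveCurvatureError,
    ValidationError,
)
from .geometry_core import (
    CurvatureTensorField,
    PlateauPlane,
    RigidTransform,
    interpolate_tensor,
    rodrigues,
)
from .surface import TriMesh

__all__ = [
    "ContactState",
    "HelicalAxis",
    "KneeGeometry",
    "Trajectory",
    "TrajectoryStep",
    "find_contact_point",
    "solve_helical_axis",
    "step_flexion",
    "compute_flexion_trajectory",
]

PENETRATION_TOL = 0.5  # mm, absorbs discretization noise in contact search
MIN_CURVATURE = 1e-6  # 1/mm


@dataclass
class ContactState:
    """Contact state of one tibiofemoral compartment.

    ``normal`` as returned by :func:`find_contact_point` is the outward
    condyle surface normal (antiparallel to the plateau normal).  After
    :func:`solve_helical_axis` it is flipped toward the condyle interior so
    the invariant I = p + r n holds with I at the osculating center.
    """

    compartment: str  # "medial" | "lateral"
    point: np.ndarray  # p, mm
    normal: np.ndarray  # n, unit
    tangent: Optional[np.ndarray] = None  # t, unit, orthogonal to n
    radius: Optional[float] = None  # r, mm, > 0
    intersection: Optional[np.ndarray] = None  # I = p + r n
    face: Optional[int] = None
    barycentric: Optional[np.ndarray] = None

    def validate(self) -> None:
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-6:
            raise ValidationError("contact normal is not unit")
        if self.tangent is not None:
            if abs(np.linalg.norm(self.tangent) - 1.0) > 1e-6:
                raise ValidationError("contact tangent is not unit")
            if abs(float(self.normal @ self.tangent)) > 1e-6:
                raise ValidationError("tangent not orthogonal to normal")
        if self.radius is not None:
            if self.radius <= 0:
                raise ValidationError("contact radius must be positive")
            if self.intersection is not None:
                expect = self.point + self.radius * self.normal
                if np.linalg.norm(expect - self.intersection) > 1e-9:
                    raise ValidationError("I != p + r n")


@dataclass
class HelicalAxis:
    """Instantaneous flexion axis through the two intersection points."""

    direction: np.ndarray  # unit
    point_medial: np.ndarray  # I_m
    point_lateral: np.ndarray  # I_l

    def __post_init__(self):
        self.direction = np.asarray(self.direction, float).reshape(3)
        n = np.linalg.norm(self.direction)
        if n < 1e-12:
            raise DegenerateAxisError("zero axis direction")
        self.direction = self.direction / n


@dataclass
class KneeGeometry:
    """Knee geometry bundle: fixed femur side, moving tibia side."""

    condyle_medial: CurvatureTensorField
    condyle_lateral: CurvatureTensorField
    plateau_medial: PlateauPlane
    plateau_lateral: PlateauPlane
    tibia_bodies: List[TriMesh] = field(default_factory=list)

    def transformed_tibia(self, transform: RigidTransform) -> "KneeGeometry":
        return KneeGeometry(
            condyle_medial=self.condyle_medial,
            condyle_lateral=self.condyle_lateral,
            plateau_medial=self.plateau_medial.transformed(transform),
            plateau_lateral=self.plateau_lateral.transformed(transform),
            tibia_bodies=[m.transformed(transform) for m in self.tibia_bodies],
        )

    def transformed_femur(self, transform: RigidTransform) -> "KneeGeometry":
        return KneeGeometry(
            condyle_medial=self.condyle_medial.rotated(transform),
            condyle_lateral=self.condyle_lateral.rotated(transform),
            plateau_medial=self.plateau_medial,
            plateau_lateral=self.plateau_lateral,
            tibia_bodies=list(self.tibia_bodies),
        )


@dataclass
class TrajectoryStep:
    axis: HelicalAxis
    angle: float  # deg, signed
    transform: RigidTransform
    contact_medial_world: np.ndarray
    contact_lateral_world: np.ndarray
    contact_medial_tibia: np.ndarray
    contact_lateral_tibia: np.ndarray


@dataclass
class Trajectory:
    """Ordered incremental flexion steps and their composition."""

    steps: List[TrajectoryStep] = field(default_factory=list)

    @property
    def cumulative_angle(self) -> float:
        return float(sum(s.angle for s in self.steps))

    @property
    def composed_transform(self) -> RigidTransform:
        T = RigidTransform.identity()
        for s in self.steps:
            T = s.transform.compose(T)
        return T

    def inverted(self) -> "Trajectory":
        """Step-by-step reversed trajectory (inverse transforms, reverse
        order); replaying it undoes this trajectory exactly."""
        out = Trajectory()
        for s in reversed(self.steps):
            out.steps.append(
                TrajectoryStep(
                    axis=s.axis,
                    angle=-s.angle,
                    transform=s.transform.inverse(),
                    contact_medial_world=s.contact_medial_world.copy(),
                    contact_lateral_world=s.contact_lateral_world.copy(),
                    contact_medial_tibia=s.contact_medial_tibia.copy(),
                    contact_lateral_tibia=s.contact_lateral_tibia.copy(),
                )
            )
        return out

    # -- export / import ------------------------------------------------
    def to_json(self, path=None):
        payload = {
            "cumulative_angle": self.cumulative_angle,
            "steps": [
                {
                    "axis_point_medial": s.axis.point_medial.tolist(),
                    "axis_point_lateral": s.axis.point_lateral.tolist(),
                    "direction": s.axis.direction.tolist(),
                    "angle": s.angle,
                    "matrix": s.transform.matrix().tolist(),
                }
                for s in self.steps
            ],
        }
        if path is None:
            return payload
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return payload

    @classmethod
    def from_json(cls, path) -> "Trajectory":
        with open(path) as fh:
            payload = json.load(fh)
        traj = cls()
        for s in payload["steps"]:
            M = np.asarray(s["matrix"], float)
            axis = HelicalAxis(
                np.asarray(s["direction"], float),
                np.asarray(s["axis_point_medial"], float),
                np.asarray(s["axis_point_lateral"], float),
            )
            zero = np.zeros(3)
            traj.steps.append(
                TrajectoryStep(
                    axis=axis,
                    angle=float(s["angle"]),
                    transform=RigidTransform(M[:3, :3], M[:3, 3]),
                    contact_medial_world=zero.copy(),
                    contact_lateral_world=zero.copy(),
                    contact_medial_tibia=zero.copy(),
                    contact_lateral_tibia=zero.copy(),
                )
            )
        return traj

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["step", "angle_deg", "ux", "uy", "uz",
                 "Imx", "Imy", "Imz", "Ilx", "Ily", "Ilz"]
            )
            for i, s in enumerate(self.steps):
                w.writerow(
                    [i, s.angle, *s.axis.direction, *s.axis.point_medial,
                     *s.axis.point_lateral]
                )


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def _bary_grid(res: float) -> np.ndarray:
    vals = np.arange(0.0, 1.0 + res / 2, res)
    grid = []
    for u in vals:
        for v in vals:
            if u + v <= 1.0 + 1e-12:
                grid.append((u, v, 1.0 - u - v))
    return np.asarray(grid)


def find_contact_point(
    condyle: CurvatureTensorField, plateau: PlateauPlane
) -> ContactState:
    """Find the condyle point whose outward normal is antiparallel to the
    plateau normal: the minimizer of signed distance to the plateau plane,
    refined by a 2-level barycentric grid search inside the minimizing
    triangles; the contact normal is the interpolated surface normal.
    """
    mesh = condyle.mesh
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise ValidationError("empty condyle mesh")
    d = plateau.signed_distance(mesh.vertices)
    imin = int(np.argmin(d))
    if d[imin] < -PENETRATION_TOL:
        warnings.warn(
            f"condyle penetrates plateau by {-d[imin]:.3f} mm; "
            "support point returned",
            RuntimeWarning,
        )
    is_medial = getattr(condyle, "compartment", None)

    # Refinement inside the triangles incident to the minimizing vertex:
    # linear position interpolation alone would always land back on the
    # vertex, so the sub-triangle tangency point is located where the
    # interpolated surface normal is antiparallel to the plateau normal
    # (misalignment 1 + n(b)·n_plane -> 0), with signed distance as the
    # tie-break.  Two-level barycentric grid, resolution 0.05 then 0.005.
    np_plane = plateau.normal
    best = None  # (misalignment, distance, face, bary)
    for fi in mesh.vertex_faces[imin]:
        tri = mesh.vertices[mesh.faces[fi]]
        vn = mesh.vertex_normals[mesh.faces[fi]]

        def objective(bary):
            nrm = bary @ vn
            nrm = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)
            return 1.0 + nrm @ np_plane

        bary = _bary_grid(0.05)
        mis = objective(bary)
        b0 = bary[int(np.argmin(mis))]
        fine = []
        for du in np.arange(-0.05, 0.0501, 0.005):
            for dv in np.arange(-0.05, 0.0501, 0.005):
                u, v = b0[0] + du, b0[1] + dv
                w = 1.0 - u - v
                if u >= -1e-12 and v >= -1e-12 and w >= -1e-12:
                    fine.append((max(u, 0.0), max(v, 0.0), max(w, 0.0)))
        fine = np.asarray(fine)
        fine = fine / fine.sum(axis=1, keepdims=True)
        mis = objective(fine)
        j = int(np.argmin(mis))
        dist = float(plateau.signed_distance(fine[j] @ tri))
        cand = (float(mis[j]), dist, int(fi), fine[j])
        if best is None or cand[:2] < best[:2]:
            best = cand

    _, dist, fi, bary = best
    p = bary @ mesh.vertices[mesh.faces[fi]]
    n = bary @ mesh.vertex_normals[mesh.faces[fi]]
    n = n / np.linalg.norm(n)
    comp = "medial" if is_medial is None else is_medial
    return ContactState(
        compartment=comp, point=p, normal=n, face=fi, barycentric=bary
    )


def solve_helical_axis(
    medial: ContactState,
    lateral: ContactState,
    field_m: CurvatureTensorField,
    field_l: CurvatureTensorField,
    max_iter: int = 100,
    tol: float = 1e-6,
):
    """Fixed-point solve for (r_m, r_l) and the instantaneous helical axis.

    Initialization: u = normalize(p_l - p_m).  Each iteration sets the
    tangents perpendicular to the current axis inside the contact tangent
    planes, reads the normal curvatures from the interpolated tensors, sets
    r = 1/kappa_n and I = p + r n_in (n_in: condyle-interior direction), and
    re-aims the axis at normalize(I_l - I_m).  Converged when the change of
    (r_m, r_l) drops below ``tol`` mm.
    """
    p_m, p_l = medial.point, lateral.point
    # condyle-interior normal directions (find_contact_point returns the
    # outward surface normal)
    n_m = -medial.normal
    n_l = -lateral.normal

    if medial.face is not None:
        C_m = interpolate_tensor(field_m, medial.face, medial.barycentric)
    else:
        C_m = field_m.tensors[int(np.argmin(
            np.linalg.norm(field_m.mesh.vertices - p_m, axis=1)))]
    if lateral.face is not None:
        C_l = interpolate_tensor(field_l, lateral.face, lateral.barycentric)
    else:
        C_l = field_l.tensors[int(np.argmin(
            np.linalg.norm(field_l.mesh.vertices - p_l, axis=1)))]

    u = p_l - p_m
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        raise DegenerateAxisError("contact points coincide")
    u = u / nu

    def tangent_of(n_in, name):
        t = np.cross(n_in, u)
        nt = np.linalg.norm(t)
        if nt < 1e-9:
            raise DegenerateAxisError(
                f"axis candidate parallel to the {name} contact normal"
            )
        return t / nt

    r_m = r_l = None
    for _ in range(max_iter):
        t_m = tangent_of(n_m, "medial")
        t_l = tangent_of(n_l, "lateral")
        k_m = float(t_m @ C_m @ t_m)
        k_l = float(t_l @ C_l @ t_l)
        if k_m <= MIN_CURVATURE:
            raise NonPositiveCurvatureError("medial", k_m)
        if k_l <= MIN_CURVATURE:
            raise NonPositiveCurvatureError("lateral", k_l)
        new_r_m, new_r_l = 1.0 / k_m, 1.0 / k_l
        I_m = p_m + new_r_m * n_m
        I_l = p_l + new_r_l * n_l
        d = I_l - I_m
        nd = np.linalg.norm(d)
        if nd < 1e-9:
            raise DegenerateAxisError(
                "intersection points coincide; helical axis undefined"
            )
        u = d / nd
        if r_m is not None and abs(new_r_m - r_m) + abs(new_r_l - r_l) < tol:
            r_m, r_l = new_r_m, new_r_l
            break
        r_m, r_l = new_r_m, new_r_l
    else:
        raise NonConvergenceError(
            "helical-axis fixed point did not converge",
            residual=abs(new_r_m - (r_m or 0)) + abs(new_r_l - (r_l or 0)),
        )

    t_m = tangent_of(n_m, "medial")
    t_l = tangent_of(n_l, "lateral")
    I_m = p_m + r_m * n_m
    I_l = p_l + r_l * n_l
    med = ContactState(
        compartment="medial", point=p_m, normal=n_m, tangent=t_m,
        radius=r_m, intersection=I_m, face=medial.face,
        barycentric=medial.barycentric,
    )
    lat = ContactState(
        compartment="lateral", point=p_l, normal=n_l, tangent=t_l,
        radius=r_l, intersection=I_l, face=lateral.face,
        barycentric=lateral.barycentric,
    )
    med.validate()
    lat.validate()
    return med, lat, HelicalAxis(u, I_m, I_l)


def step_flexion(
    geometry: KneeGeometry, axis: HelicalAxis, delta: float
):
    """Rotate all tibia-side entities by ``delta`` degrees about the axis.

    Femur-side entities are untouched.  |delta| must be in (0, 5].
    """
    if not (0 < abs(delta) <= 5.0):
        raise ValidationError("step angle must satisfy 0 < |delta| <= 5 deg")
    T = rodrigues(axis.direction, delta, axis.point_medial)
    return geometry.transformed_tibia(T), T


def compute_flexion_trajectory(
    geometry: KneeGeometry,
    target_angle: float,
    step: float = 0.5,
    offset_hook: Optional[Callable] = None,
) -> Trajectory:
    """Iterate contact search -> axis solve -> rotation until the target.

    The last step is truncated to land exactly on ``target_angle``.
    Negative targets run the same loop in extension.  ``offset_hook``
    (optional) maps a step index to a pair of 2D offsets applied to
    (I_m, I_l) in the (tangent, axis) frame before rotating — the
    experimental contact-trace hook; default zero keeps the geometrically
    neutral path.

    Inner-operation failures re-raise with the partial trajectory attached
    as ``exc.partial_trajectory``.
    """
    if target_angle == 0:
        raise ValidationError("target angle must be non-zero")
    if step <= 0:
        raise ValidationError("step must be positive")
    sign = 1.0 if target_angle > 0 else -1.0
    remaining = abs(target_angle)
    traj = Trajectory()
    cumulative = RigidTransform.identity()
    geom = geometry
    step_index = 0
    try:
        while remaining > 1e-12:
            delta = min(step, remaining)
            contact_m = find_contact_point(geom.condyle_medial,
                                           geom.plateau_medial)
            contact_m.compartment = "medial"
            contact_l = find_contact_point(geom.condyle_lateral,
                                           geom.plateau_lateral)
            contact_l.compartment = "lateral"
            med, lat, axis = solve_helical_axis(
                contact_m, contact_l, geom.condyle_medial, geom.condyle_lateral
            )
            if offset_hook is not None:
                off = offset_hook(step_index)
                if off is not None:
                    (am, bm), (al, bl) = off
                    I_m = axis.point_medial + am * med.tangent + bm * axis.direction
                    I_l = axis.point_lateral + al * lat.tangent + bl * axis.direction
                    axis = HelicalAxis(I_l - I_m, I_m, I_l)
            inv = cumulative.inverse()
            geom, T = step_flexion(geom, axis, sign * delta)
            traj.steps.append(
                TrajectoryStep(
                    axis=axis,
                    angle=sign * delta,
                    transform=T,
                    contact_medial_world=med.point.copy(),
                    contact_lateral_world=lat.point.copy(),
                    contact_medial_tibia=inv.apply(med.point),
                    contact_lateral_tibia=inv.apply(lat.point),
                )
            )
            cumulative = T.compose(cumulative)
            remaining -= delta
            step_index += 1
    except ArthroposeError as exc:
        exc.partial_trajectory = traj
        raise
    return traj
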