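"""Joint parameterization and kinematic-chain skeleton reconfiguration.

Ball joints (shoulder/hip) rotate about least-squares sphere centers with an
intrinsic internal/external -> flexion/extension -> adduction/abduction
Euler sequence (or an explicit 3x3 matrix); the elbow rotates in-plane about
the fitted trochlear-notch cylinder axis (the radius follows the ulna via
the driven-part list); the knee follows its geometry-derived flexion
trajectory; spine rotations are split evenly across the vertebrae and
compounded caudal -> cranial about per-vertebra centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .errors import ValidationError
from .fe_model_io import FEModel, extract_surface
from .geometry_core import (
    PlateauPlane,
    RigidTransform,
    curvature_tensor_field,
    euler_intrinsic,
    fit_cylinder,
    fit_plane,
    fit_sphere,
    rodrigues,
)
from .knee_trajectory import KneeGeometry, Trajectory, compute_flexion_trajectory
from .surface import TriMesh

__all__ = [
    "JointDefinition",
    "PoseParameters",
    "SkeletonResult",
    "build_joint_definitions",
    "vertebra_center",
    "spine_transforms",
    "reconfigure_skeleton",
]

_GLOBAL_AXES = np.array(
    [[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]]
)  # internal/external, flexion/extension, adduction/abduction


@dataclass
class JointDefinition:
    name: str
    type: str  # ball | hinge | knee | spine
    center: Optional[np.ndarray] = None
    axis: Optional[np.ndarray] = None
    fitted_radius: Optional[float] = None
    driven_parts: List[int] = field(default_factory=list)
    child_joints: List[str] = field(default_factory=list)
    axes: Optional[np.ndarray] = None  # anatomical axes override (3 rows)
    knee_geometry: Optional[KneeGeometry] = None
    vertebrae: Optional[List[Dict]] = None  # spine: [{part, center}], caudal first
    config: Dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.driven_parts and self.type != "spine":
            raise ValidationError(f"joint {self.name!r} has no driven parts")
        if self.type == "hinge":
            if self.axis is None or abs(np.linalg.norm(self.axis) - 1) > 1e-9:
                raise ValidationError(f"hinge {self.name!r} needs a unit axis")


@dataclass
class PoseParameters:
    """Per-joint pose values, degrees.

    Values: scalar flexion for hinge/knee joints, a 3-sequence of intrinsic
    angles or a 3x3 rotation matrix for ball joints, a scalar (flexion) or
    3-sequence for spine joints.  Absent joints default to identity.
    """

    values: Dict[str, object] = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "PoseParameters":
        with open(path) as fh:
            data = json.load(fh)
        out = {}
        for k, v in data.items():
            out[k] = np.asarray(v, float) if isinstance(v, list) else float(v)
        return cls(values=out)

    def angle(self, joint: str):
        return self.values.get(joint, 0.0)

    def posed_joints(self):
        return [k for k, v in self.values.items() if np.any(np.asarray(v) != 0)]

    def negated(self) -> "PoseParameters":
        out = {}
        for k, v in self.values.items():
            arr = np.asarray(v, float)
            if arr.shape == (3, 3):
                out[k] = arr.T
            else:
                out[k] = -arr if arr.ndim else -float(arr)
        return PoseParameters(values=out)


# ----------------------------------------------------------------------

def vertebra_center(model: FEModel, vertebra_part: int,
                    top_set: int, bottom_set: int) -> np.ndarray:
    """Midpoint of the top-face and bottom-face node centroids."""
    top = model.node_sets.get(top_set)
    bottom = model.node_sets.get(bottom_set)
    if not top or not bottom:
        raise ValidationError(
            f"vertebra part {vertebra_part}: empty top/bottom node set"
        )
    ct = model.coords_of(top).mean(axis=0)
    cb = model.coords_of(bottom).mean(axis=0)
    return (ct + cb) / 2.0


def _crop_to_nodes(mesh: TriMesh, node_ids) -> TriMesh:
    """Sub-mesh of faces whose three vertices are all in ``node_ids``."""
    wanted = set(int(n) for n in node_ids)
    keep = np.array(
        [all(int(mesh.source_node_ids[v]) in wanted for v in f)
         for f in mesh.faces]
    )
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(
        mesh.vertices[used], remap[faces],
        source_node_ids=mesh.source_node_ids[used],
    )


def _build_knee_geometry(model: FEModel, entry: Dict) -> KneeGeometry:
    part = entry.get("condyle_part")
    surf = extract_surface(model, part)
    cm = _crop_to_nodes(surf, model.node_sets[entry["condyle_medial_set"]])
    cl = _crop_to_nodes(surf, model.node_sets[entry["condyle_lateral_set"]])
    field_m = curvature_tensor_field(cm)
    field_l = curvature_tensor_field(cl)
    field_m.compartment = "medial"
    field_l.compartment = "lateral"

    def plateau_from(set_id, condyle_mesh):
        pts = model.coords_of(model.node_sets[set_id])
        plane = fit_plane(pts)
        toward = condyle_mesh.vertices.mean(axis=0) - plane.point
        if plane.normal @ toward < 0:
            plane = PlateauPlane(plane.point, -plane.normal)
        return plane

    return KneeGeometry(
        condyle_medial=field_m,
        condyle_lateral=field_l,
        plateau_medial=plateau_from(entry["plateau_medial_set"], cm),
        plateau_lateral=plateau_from(entry["plateau_lateral_set"], cl),
        tibia_bodies=[],
    )


def build_joint_definitions(model: FEModel, config: Dict) -> Dict[str, JointDefinition]:
    """Build joint definitions from the model geometry and a config dict.

    Config: ``{"joints": {name: {type, ...sets/parts, driven_parts,
    child_joints, [axes]}}}`` (YAML/JSON-loadable).  Ball joints fit spheres
    to their articular node sets, hinges fit cylinders, knees assemble
    condyle/plateau geometry, spines collect per-vertebra centers.
    """
    joints: Dict[str, JointDefinition] = {}
    for name, entry in config.get("joints", {}).items():
        jtype = entry["type"]
        axes = np.asarray(entry["axes"], float) if "axes" in entry else None
        common = dict(
            name=name, type=jtype,
            driven_parts=list(entry.get("driven_parts", [])),
            child_joints=list(entry.get("child_joints", [])),
            axes=axes, config=entry,
        )
        if jtype == "ball":
            sid = entry["surface_set"]
            if sid not in model.node_sets:
                raise ValidationError(f"joint {name!r}: missing node set {sid}")
            center, radius = fit_sphere(model.coords_of(model.node_sets[sid]))
            joints[name] = JointDefinition(center=center, fitted_radius=radius,
                                           **common)
        elif jtype == "hinge":
            sid = entry["surface_set"]
            if sid not in model.node_sets:
                raise ValidationError(f"joint {name!r}: missing node set {sid}")
            point, axis, radius = fit_cylinder(
                model.coords_of(model.node_sets[sid])
            )
            joints[name] = JointDefinition(center=point, axis=axis,
                                           fitted_radius=radius, **common)
        elif jtype == "knee":
            geom = _build_knee_geometry(model, entry)
            joints[name] = JointDefinition(knee_geometry=geom, **common)
        elif jtype == "spine":
            verts = []
            for v in entry["vertebrae"]:
                verts.append({
                    "part": v["part"],
                    "center": vertebra_center(model, v["part"], v["top_set"],
                                              v["bottom_set"]),
                })
            joints[name] = JointDefinition(vertebrae=verts, **common)
        else:
            raise ValidationError(f"joint {name!r}: unknown type {jtype!r}")
    return joints


def spine_transforms(centers, rotation, n_segments: int,
                     axes: Optional[np.ndarray] = None) -> List[RigidTransform]:
    """Per-vertebra transforms for an evenly split spine rotation.

    ``rotation`` is either (axis, total_angle_deg) or a 3-sequence of
    intrinsic angles (split per-axis).  Vertebra k (caudal -> cranial)
    receives the composition of segments 1..k, each segment rotating about
    its own (already-moved) center via the Rodrigues formula.
    """
    centers = [np.asarray(c, float) for c in centers]
    if n_segments != len(centers) or n_segments < 1:
        raise ValidationError("n_segments must equal the number of centers (>= 1)")
    if axes is None:
        axes = _GLOBAL_AXES
    cumulative = RigidTransform.identity()
    out: List[RigidTransform] = []
    for c in centers:
        c_moved = cumulative.apply(c)
        if isinstance(rotation, tuple) and len(rotation) == 2 and \
                np.ndim(rotation[1]) == 0:
            axis, total = rotation
            axis_moved = cumulative.apply_vector(np.asarray(axis, float))
            seg = rodrigues(axis_moved, float(total) / n_segments, c_moved)
        else:
            angles = np.asarray(rotation, float).reshape(3) / n_segments
            axes_moved = cumulative.apply_vector(axes)
            R = euler_intrinsic(angles[0], angles[1], angles[2], axes_moved)
            seg = RigidTransform(R, c_moved - R @ c_moved)
        cumulative = seg.compose(cumulative)
        out.append(cumulative)
    return out


@dataclass
class SkeletonResult:
    part_transforms: Dict[int, RigidTransform]
    trajectories: Dict[str, Trajectory] = field(default_factory=dict)
    joint_transforms: Dict[str, RigidTransform] = field(default_factory=dict)

    def transform_of(self, part_id: int) -> RigidTransform:
        return self.part_transforms.get(part_id, RigidTransform.identity())

    def inverse(self) -> "SkeletonResult":
        """Exact reversal: inverse part transforms; knee trajectories are
        reversed step-by-step."""
        return SkeletonResult(
            part_transforms={p: t.inverse()
                             for p, t in self.part_transforms.items()},
            trajectories={k: t.inverted() for k, t in self.trajectories.items()},
            joint_transforms={k: t.inverse()
                              for k, t in self.joint_transforms.items()},
        )


def _check_acyclic(joints: Dict[str, JointDefinition]) -> List[str]:
    """Return root joint names; raise on cycles or unknown children."""
    children: set = set()
    for j in joints.values():
        for c in j.child_joints:
            if c not in joints:
                raise ValidationError(
                    f"joint {j.name!r} lists unknown child {c!r}"
                )
            children.add(c)
    roots = [n for n in joints if n not in children]
    seen: set = set()

    def visit(name, stack):
        if name in stack:
            raise ValidationError(f"cyclic joint chain at {name!r}")
        if name in seen:
            return
        seen.add(name)
        for c in joints[name].child_joints:
            visit(c, stack | {name})

    for r in roots:
        visit(r, set())
    if len(seen) != len(joints):
        raise ValidationError("cyclic joint chain (no reachable root)")
    return roots


def _ball_rotation(value, axes) -> np.ndarray:
    arr = np.asarray(value, float)
    if arr.shape == (3, 3):
        return arr
    if arr.shape == (3,):
        return euler_intrinsic(arr[0], arr[1], arr[2], axes)
    if arr.ndim == 0:
        return euler_intrinsic(0.0, float(arr), 0.0, axes)
    raise ValidationError("ball joint pose must be 3 angles or a 3x3 matrix")


def reconfigure_skeleton(
    model: FEModel,
    joints: Dict[str, JointDefinition],
    pose: PoseParameters,
    step: float = 0.5,
) -> SkeletonResult:
    """Propagate pose parameters down the kinematic chains.

    Root parts stay fixed; each joint's local rotation is computed about its
    center/axis/geometry as moved by all proximal joints, then composed onto
    the transforms of its driven parts and every distal joint.  Knee
    transforms come from the geometry-derived flexion trajectory computed in
    the parent-moved frame.
    """
    for name in pose.posed_joints():
        if name not in joints:
            raise ValidationError(f"pose references undefined joint {name!r}")
    roots = _check_acyclic(joints)
    result = SkeletonResult(part_transforms={})

    def recurse(name: str, parent: RigidTransform):
        j = joints[name]
        value = pose.angle(name)
        axes = j.axes if j.axes is not None else _GLOBAL_AXES
        if j.type == "spine":
            _apply_spine(j, value, parent, result)
            cumulative = result.joint_transforms[name]
        else:
            if j.type == "ball":
                if np.any(np.asarray(value) != 0):
                    R = _ball_rotation(value, parent.apply_vector(axes))
                    c = parent.apply(j.center)
                    local = RigidTransform(R, c - R @ c)
                else:
                    local = RigidTransform.identity()
            elif j.type == "hinge":
                ang = float(np.asarray(value))
                if ang != 0.0:
                    local = rodrigues(parent.apply_vector(j.axis), ang,
                                      parent.apply(j.center))
                else:
                    local = RigidTransform.identity()
            elif j.type == "knee":
                ang = float(np.asarray(value))
                if ang != 0.0:
                    geom = _moved_knee_geometry(j.knee_geometry, parent)
                    traj = compute_flexion_trajectory(geom, ang, step=step)
                    result.trajectories[name] = traj
                    local = traj.composed_transform
                else:
                    local = RigidTransform.identity()
            else:
                raise ValidationError(f"unknown joint type {j.type!r}")
            cumulative = local.compose(parent)
            result.joint_transforms[name] = cumulative
            for pid in j.driven_parts:
                result.part_transforms[pid] = cumulative
        for child in j.child_joints:
            recurse(child, cumulative)

    for r in roots:
        recurse(r, RigidTransform.identity())
    return result


def _moved_knee_geometry(geom: KneeGeometry, parent: RigidTransform) -> KneeGeometry:
    if parent.is_identity():
        return geom
    # femur-side condyles move with the parent chain; the plateaus sit on
    # the (not yet moved) tibia but must start in contact, so they are
    # carried along as well — the knee trajectory is relative to the femur.
    moved = geom.transformed_femur(parent)
    return KneeGeometry(
        condyle_medial=moved.condyle_medial,
        condyle_lateral=moved.condyle_lateral,
        plateau_medial=geom.plateau_medial.transformed(parent),
        plateau_lateral=geom.plateau_lateral.transformed(parent),
        tibia_bodies=[m.transformed(parent) for m in geom.tibia_bodies],
    )


def _apply_spine(j: JointDefinition, value, parent: RigidTransform,
                 result: SkeletonResult) -> None:
    centers = [parent.apply(v["center"]) for v in j.vertebrae]
    arr = np.asarray(value, float)
    axes = j.axes if j.axes is not None else _GLOBAL_AXES
    # a scalar means flexion only (thoracic); 3 angles are split per-axis
    # in the intrinsic order (lumbar)
    if arr.ndim == 0:
        angles = np.array([0.0, float(arr), 0.0])
    else:
        angles = arr.reshape(3)
    transforms = spine_transforms(centers, angles, len(centers), axes=axes)
    for vert, t in zip(j.vertebrae, transforms):
        result.part_transforms[vert["part"]] = t.compose(parent)
    result.joint_transforms[j.name] = transforms[-1].compose(parent)


def apply_skeleton_transforms(model: FEModel, result: SkeletonResult) -> FEModel:
    """Return a model copy with every driven part rigidly transformed."""
    out = model.copy()
    for pid, t in result.part_transforms.items():
        if t.is_identity():
            continue
        out.transform_nodes(out.part_node_ids(pid), t)
    return out
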