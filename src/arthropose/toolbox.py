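"""Pipeline orchestration: skeleton reconfiguration -> per-joint
morph-contact -> flesh TPS -> quality audit."""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .errors import ArthroposeError, ValidationError
from .fe_model_io import FEModel, extract_surface
from .geometry_core import RigidTransform
from .joint_library import (
    JointDefinition,
    PoseParameters,
    SkeletonResult,
    apply_skeleton_transforms,
    build_joint_definitions,
    reconfigure_skeleton,
)
from .knee_trajectory import Trajectory
from .mesh_quality import QualityReport, quality_report
from .morph_contact import (
    detect_penetrations,
    preliminary_morph,
    reduced_bone_landmarks,
    refine_interface,
    resolve_penetrations,
    segment_capsule,
)
from .proximity import signed_distance
from .surface import write_surface
from .tps_morph import apply_tps, fit_tps

__all__ = ["RunConfig", "RepositionResult", "reposition", "StageError"]

logger = logging.getLogger("arthropose")


@dataclass
class RunConfig:
    step: float = 0.5  # knee trajectory step, deg
    tps_lambda: float = 0.0
    refine_weights: tuple = (1.0, 0.1, 0.01)  # w_c, w_e, w_n
    refine_iters: int = 300
    segment_tol: float = 1.0  # mm
    landmark_fraction: float = 0.1
    seed: int = 0
    debug_dir: Optional[str] = None
    thresholds: Optional[Dict[str, float]] = None

    def validate(self) -> None:
        if not (0 < self.step <= 5):
            raise ValidationError("step must be in (0, 5] degrees")
        if self.tps_lambda < 0:
            raise ValidationError("tps_lambda must be >= 0")


@dataclass
class RepositionResult:
    model: FEModel
    report: QualityReport
    trajectories: Dict[str, Trajectory] = field(default_factory=dict)
    skeleton: Optional[SkeletonResult] = None


class StageError(ArthroposeError):
    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage {stage!r} failed: {original}")


def _timed(stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.time() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2f s", stage, dt)
            else:
                logger.error("stage %s: failed after %.2f s: %s", stage, dt, exc)
            return False

    return _Ctx()


def _verify_bone_rigidity(model: FEModel, out: FEModel, part_ids,
                          rel_tol: float = 1e-9) -> None:
    rng = np.random.default_rng(0)
    for pid in part_ids:
        nids = model.part_node_ids(pid)
        if len(nids) < 2:
            continue
        sel = rng.choice(len(nids), size=min(40, len(nids)), replace=False)
        ids = [nids[i] for i in sel]
        a = model.coords_of(ids)
        b = out.coords_of(ids)
        da = np.linalg.norm(a[:, None] - a[None], axis=2)
        db = np.linalg.norm(b[:, None] - b[None], axis=2)
        scale = max(da.max(), 1.0)
        if np.abs(da - db).max() > rel_tol * scale * 10:
            raise ValidationError(
                f"bone part {pid} is not rigid after repositioning"
            )


def reposition(model: FEModel, joints_config: Dict, pose: PoseParameters,
               config: Optional[RunConfig] = None) -> RepositionResult:
    """Full repositioning pipeline.

    1. bones via the kinematic chain (knee: geometry-derived trajectory);
    2. each synovial joint capsule via morph-contact (preliminary TPS,
       penetration resolve, interface refinement);
    3. spine-attached tissues via plain TPS;
    4. flesh via TPS on the boundary landmarks;
    5. quality audit + bone-rigidity verification.
    """
    config = config or RunConfig()
    config.validate()
    if config.debug_dir:
        os.makedirs(config.debug_dir, exist_ok=True)

    with _timed("validate"):
        model.validate()
        joints = build_joint_definitions(model, joints_config)

    try:
        with _timed("skeleton"):
            skeleton = reconfigure_skeleton(model, joints, pose,
                                            step=config.step)
            out = apply_skeleton_transforms(model, skeleton)
    except ArthroposeError as exc:
        raise StageError("skeleton", exc) from exc

    bone_parts = sorted({p for j in joints.values()
                         for p in (j.driven_parts or [])}
                        | {v["part"] for j in joints.values()
                           if j.vertebrae for v in j.vertebrae})

    for name, j in joints.items():
        entry = j.config
        if "capsule_part" not in entry:
            continue
        try:
            with _timed(f"morph_contact[{name}]"):
                out = _morph_contact_joint(model, out, j, skeleton, config)
        except ArthroposeError as exc:
            if config.debug_dir:
                logger.error("saving partial artifacts to %s", config.debug_dir)
            raise StageError(f"morph_contact[{name}]", exc) from exc

    for name, j in joints.items():
        if j.type == "spine" and j.config.get("flesh_parts"):
            try:
                with _timed(f"spine_tissue[{name}]"):
                    out = _spine_tissue(model, out, j, skeleton, config)
            except ArthroposeError as exc:
                raise StageError(f"spine_tissue[{name}]", exc) from exc

    with _timed("audit"):
        _verify_bone_rigidity(model, out, bone_parts)
        report = quality_report(out, thresholds=config.thresholds)

    return RepositionResult(model=out, report=report,
                            trajectories=skeleton.trajectories,
                            skeleton=skeleton)


def _morph_contact_joint(model: FEModel, out: FEModel, j: JointDefinition,
                         skeleton: SkeletonResult,
                         config: RunConfig) -> FEModel:
    entry = j.config
    prox_pid = entry["proximal_part"]
    dist_pid = entry["distal_part"]
    capsule_pid = entry["capsule_part"]
    flesh_parts = entry.get("flesh_parts", [])
    T_p = skeleton.transform_of(prox_pid)
    T_d = skeleton.transform_of(dist_pid)
    if T_p.is_identity() and T_d.is_identity():
        return out

    capsule = extract_surface(model, capsule_pid)
    femur = extract_surface(model, prox_pid)
    tibia = extract_surface(model, dist_pid)

    seg = segment_capsule(capsule, femur, tibia, tol=config.segment_tol)

    # baseline orientation signs (pre-morph configuration)
    base_f = signed_distance(capsule, femur.vertices)[0]
    base_t = signed_distance(capsule, tibia.vertices)[0]

    src_f, tgt_f = reduced_bone_landmarks(
        femur, T_p, tibia.vertices.mean(axis=0),
        fraction=config.landmark_fraction, seed=config.seed,
    )
    src_t, tgt_t = reduced_bone_landmarks(
        tibia, T_d, femur.vertices.mean(axis=0),
        fraction=config.landmark_fraction, seed=config.seed,
    )
    reduced = (np.vstack([src_f, src_t]), np.vstack([tgt_f, tgt_t]))
    morphed = preliminary_morph(capsule, reduced, segmentation=seg,
                                proximal_transform=T_p, distal_transform=T_d)
    if config.debug_dir:
        write_surface(morphed, os.path.join(config.debug_dir,
                                            f"{j.name}_preliminary.obj"))

    femur_moved = femur.transformed(T_p)
    tibia_moved = tibia.transformed(T_d)
    current = morphed
    for bone, base in ((femur_moved, base_f), (tibia_moved, base_t)):
        rep = detect_penetrations(bone, current, baseline_signs=base)
        if not rep.is_empty:
            current = resolve_penetrations(current, rep,
                                           fixed=seg.fixed_nodes)
    # cross-check both bones once more (a pull for one bone can graze the
    # other)
    for bone, base in ((femur_moved, base_f), (tibia_moved, base_t)):
        rep = detect_penetrations(bone, current, baseline_signs=base)
        if not rep.is_empty:
            current = resolve_penetrations(current, rep,
                                           fixed=seg.fixed_nodes)
    if config.debug_dir:
        write_surface(current, os.path.join(config.debug_dir,
                                            f"{j.name}_resolved.obj"))

    w_c, w_e, w_n = config.refine_weights
    refined = refine_interface(current, current, fixed=seg.fixed_nodes,
                               w_c=w_c, w_e=w_e, w_n=w_n,
                               max_iter=config.refine_iters)
    for bone, base in ((femur_moved, base_f), (tibia_moved, base_t)):
        rep = detect_penetrations(bone, refined, baseline_signs=base)
        if not rep.is_empty:
            refined = resolve_penetrations(refined, rep,
                                           fixed=seg.fixed_nodes)
    if config.debug_dir:
        write_surface(refined, os.path.join(config.debug_dir,
                                            f"{j.name}_refined.obj"))

    # boundary landmarks: full capsule contour + bone surface nodes
    src = np.vstack([capsule.vertices, femur.vertices, tibia.vertices])
    tgt = np.vstack([refined.vertices, femur_moved.vertices,
                     tibia_moved.vertices])
    exact = {int(nid): refined.vertices[k]
             for k, nid in enumerate(capsule.source_node_ids)}

    from .morph_contact import deform_soft_tissue

    out = deform_soft_tissue(out, (src, tgt), flesh_parts,
                             exact_targets=exact, lam=config.tps_lambda)
    return out


def _spine_tissue(model: FEModel, out: FEModel, j: JointDefinition,
                  skeleton: SkeletonResult, config: RunConfig) -> FEModel:
    """Plain TPS for spine-attached tissues (no sliding interface)."""
    src_list, tgt_list = [], []
    for v in j.vertebrae:
        t = skeleton.transform_of(v["part"])
        nids = model.part_node_ids(v["part"])
        coords = model.coords_of(nids)
        src_list.append(coords)
        tgt_list.append(t.apply(coords))
    src = np.vstack(src_list)
    tgt = np.vstack(tgt_list)
    tps = fit_tps(src, tgt, lam=config.tps_lambda)
    flesh = j.config["flesh_parts"]
    nids: set = set()
    for pid in flesh:
        nids.update(out.part_node_ids(pid))
    nids = sorted(nids)
    out = out.copy()
    out.set_coords(nids, apply_tps(tps, out.coords_of(nids)))
    return out
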