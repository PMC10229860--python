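import copy

import numpy as np
import pytest

from arthropose.errors import ValidationError
from arthropose.fe_model_io import FEModel
from arthropose.geometry_core import RigidTransform, rodrigues
from arthropose.joint_library import (
    PoseParameters,
    apply_skeleton_transforms,
    build_joint_definitions,
    reconfigure_skeleton,
    spine_transforms,
    vertebra_center,
)
from arthropose.synthetic_fixtures import make_spine_column


@pytest.fixture(scope="module")
def limb_joints(toy_limb):
    return build_joint_definitions(toy_limb.model, toy_limb.config)


class TestBuildJointDefinitions:
    def test_ball_center_exact(self, toy_limb, limb_joints):
        truth = toy_limb.truth
        hip = limb_joints["hip"]
        assert np.linalg.norm(hip.center - truth["head_center"]) < 1e-6
        assert hip.fitted_radius == pytest.approx(truth["head_radius"],
                                                  abs=1e-6)

    def test_hinge_axis_from_notch(self):
        # synthetic trochlear-notch arc node set
        m = FEModel()
        m.parts[1] = "ulna"
        th = np.linspace(-np.pi / 3, np.pi / 3, 12)
        k = 1
        nids = []
        for z in np.linspace(0, 12, 6):
            for t in th:
                m.nodes[k] = np.array([8 * np.cos(t), 8 * np.sin(t), z])
                nids.append(k)
                k += 1
        m.shells[1] = (1, (1, 2, 3))
        m.node_sets[5] = nids
        config = {"joints": {"elbow": {"type": "hinge", "surface_set": 5,
                                       "driven_parts": [1],
                                       "child_joints": []}}}
        joints = build_joint_definitions(m, config)
        axis = joints["elbow"].axis
        assert abs(abs(axis[2]) - 1.0) < np.radians(0.5)
        assert joints["elbow"].fitted_radius == pytest.approx(8.0, abs=0.1)

    def test_missing_joint_errors_at_reposition(self, toy_limb, limb_joints):
        pose = PoseParameters(values={"ankle": 10.0})
        with pytest.raises(ValidationError, match="ankle"):
            reconfigure_skeleton(toy_limb.model, limb_joints, pose)

    def test_missing_set_errors(self, toy_limb):
        config = {"joints": {"hip": {"type": "ball", "surface_set": 999,
                                     "driven_parts": [1]}}}
        with pytest.raises(ValidationError, match="999"):
            build_joint_definitions(toy_limb.model, config)


class TestVertebraCenter:
    def test_midpoint(self):
        m = FEModel()
        m.nodes[1] = np.array([1.0, 0, 10.0])
        m.nodes[2] = np.array([-1.0, 0, 10.0])
        m.nodes[3] = np.array([0.0, 1.0, 0.0])
        m.nodes[4] = np.array([0.0, -1.0, 0.0])
        m.node_sets[1] = [1, 2]
        m.node_sets[2] = [3, 4]
        c = vertebra_center(m, 7, top_set=1, bottom_set=2)
        assert np.allclose(c, [0, 0, 5.0])

    def test_symmetric_fixture_on_axis(self):
        col = make_spine_column(3)
        for v, truth in zip(col.config["vertebrae"], col.truth["centers"]):
            c = vertebra_center(col.model, v["part"], v["top_set"],
                                v["bottom_set"])
            assert np.linalg.norm(c - truth) < 1e-9
            assert abs(c[0]) < 1e-9 and abs(c[1]) < 1e-9

    def test_single_node_sets(self):
        m = FEModel()
        m.nodes[1] = np.array([2.0, 0, 8.0])
        m.nodes[2] = np.array([0.0, 2.0, 0.0])
        m.node_sets[1] = [1]
        m.node_sets[2] = [2]
        assert np.allclose(vertebra_center(m, 1, 1, 2), [1.0, 1.0, 4.0])

    def test_empty_set_error(self):
        m = FEModel()
        m.nodes[1] = np.zeros(3)
        m.node_sets[1] = [1]
        m.node_sets[2] = []
        with pytest.raises(ValidationError):
            vertebra_center(m, 1, 1, 2)


class TestSpineTransforms:
    def test_even_split_angles(self):
        centers = [np.array([0, 0, 8.0 * k]) for k in range(5)]
        out = spine_transforms(centers, (np.array([0, 1, 0.0]), 25.0), 5)
        assert out[-1].rotation_angle() == pytest.approx(25.0, abs=1e-9)
        assert out[0].rotation_angle() == pytest.approx(5.0, abs=1e-9)

    def test_zero_rotation_identity(self):
        centers = [np.array([0, 0, 8.0 * k]) for k in range(4)]
        for t in spine_transforms(centers, (np.array([0, 1, 0.0]), 0.0), 4):
            assert t.is_identity(tol=1e-12)

    def test_sequential_composition_oracle(self):
        centers = [np.array([0, 0, 10.0 * k]) for k in range(5)]
        out = spine_transforms(centers, (np.array([0, 1, 0.0]), 90.0), 5)
        # independent brute force: apply the 5 rotations sequentially to the
        # cranial-most center, rotating each subsequent pivot/axis along
        p = centers[-1].copy()
        pivots = [c.copy() for c in centers]
        axis = np.array([0, 1, 0.0])
        for k in range(5):
            T = rodrigues(axis, 18.0, pivots[k])
            p = T.apply(p)
            for j in range(k + 1, 5):
                pivots[j] = T.apply(pivots[j])
            axis = T.apply_vector(axis)
        assert np.linalg.norm(out[-1].apply(centers[-1]) - p) < 1e-9

    def test_three_angle_per_axis_split(self):
        centers = [np.array([0, 0, 8.0 * k]) for k in range(3)]
        out = spine_transforms(centers, np.array([9.0, 15.0, 6.0]), 3)
        from arthropose.geometry_core import euler_intrinsic

        R_seg = euler_intrinsic(3.0, 5.0, 2.0)
        assert np.allclose(out[0].rotation, R_seg, atol=1e-12)


class TestReconfigureSkeleton:
    def test_zero_pose_identity(self, toy_limb, limb_joints):
        res = reconfigure_skeleton(toy_limb.model, limb_joints,
                                   PoseParameters())
        for t in res.part_transforms.values():
            assert t.is_identity(tol=1e-12)

    def test_elbow_like_single_hinge(self):
        m = FEModel()
        m.parts[1] = "upper"
        m.parts[2] = "forearm"
        m.parts[3] = "radius"
        k = 1
        upper, fore = [], []
        for z in range(3):
            m.nodes[k] = np.array([0.0, 0, 10.0 + z])
            upper.append(k)
            k += 1
        for z in range(3):
            m.nodes[k] = np.array([0.0, 0, -1.0 - z])
            fore.append(k)
            k += 1
        m.nodes[k] = np.array([1.0, 0, -2.0])
        radius_node = k
        k += 1
        th = np.linspace(-1, 1, 10)
        notch = []
        for y in (-2.0, 2.0):
            for t in th:
                m.nodes[k] = np.array([3 * np.sin(t), y, 3 * np.cos(t)])
                notch.append(k)
                k += 1
        m.shells[1] = (1, tuple(upper))
        m.shells[2] = (2, tuple(fore))
        m.shells[3] = (3, (radius_node, fore[0], fore[1]))
        m.node_sets[9] = notch
        config = {"joints": {"elbow": {
            "type": "hinge", "surface_set": 9,
            "driven_parts": [2, 3],  # radius follows the ulna
            "child_joints": []}}}
        joints = build_joint_definitions(m, config)
        res = reconfigure_skeleton(
            m, joints, PoseParameters(values={"elbow": 90.0}))
        assert 1 not in res.part_transforms  # upper arm untouched
        T = res.part_transforms[2]
        assert T.rotation_angle() == pytest.approx(90.0, abs=1e-6)
        assert res.part_transforms[3].matrix() == pytest.approx(T.matrix())
        # rotation is about the fitted notch axis (parallel y, through ~0,0,0)
        assert abs(T.rotation_axis() @ np.array([0, 1, 0.0])) > 0.999

    def test_hip_plus_knee_sequential_oracle(self, toy_limb, limb_joints):
        pose = PoseParameters(values={"hip": (0.0, 30.0, 0.0), "knee": 10.0})
        res = reconfigure_skeleton(toy_limb.model, limb_joints, pose)
        T_hip = res.part_transforms[1]
        T_tib = res.part_transforms[2]
        traj = res.trajectories["knee"]
        # brute-force sequential application: hip first, then the recorded
        # knee steps in order
        nids = toy_limb.model.part_node_ids(2)[:25]
        pts = toy_limb.model.coords_of(nids)
        seq = T_hip.apply(pts)
        for s in traj.steps:
            seq = s.transform.apply(seq)
        assert np.abs(T_tib.apply(pts) - seq).max() < 1e-9
        # hip rotation is exactly 30 deg about the fitted head center
        assert T_hip.rotation_angle() == pytest.approx(30.0, abs=1e-9)
        head = toy_limb.truth["head_center"]
        assert np.linalg.norm(T_hip.apply(head) - head) < 1e-6

    def test_bone_isometry(self, toy_limb, limb_joints):
        pose = PoseParameters(values={"knee": 10.0})
        res = reconfigure_skeleton(toy_limb.model, limb_joints, pose)
        out = apply_skeleton_transforms(toy_limb.model, res)
        nids = toy_limb.model.part_node_ids(2)[::20]
        a = toy_limb.model.coords_of(nids)
        b = out.coords_of(nids)
        da = np.linalg.norm(a[:, None] - a[None], axis=2)
        db = np.linalg.norm(b[:, None] - b[None], axis=2)
        assert np.abs(da - db).max() < 1e-9 * max(1.0, da.max())

    def test_reverse_returns_to_origin(self, toy_limb, limb_joints):
        pose = PoseParameters(values={"hip": (5.0, 20.0, 10.0),
                                      "knee": 10.0})
        res = reconfigure_skeleton(toy_limb.model, limb_joints, pose)
        posed = apply_skeleton_transforms(toy_limb.model, res)
        back = apply_skeleton_transforms(posed, res.inverse())
        for pid in (1, 2):
            nids = toy_limb.model.part_node_ids(pid)[::10]
            assert np.abs(back.coords_of(nids)
                          - toy_limb.model.coords_of(nids)).max() < 1e-6

    def test_mirror_symmetry(self, toy_limb, limb_joints):
        # mirror y -> -y; medial/lateral set labels swap; same knee angle
        mirrored = toy_limb.model.copy()
        for nid in mirrored.nodes:
            mirrored.nodes[nid] = mirrored.nodes[nid] * np.array([1, -1, 1])
        config_m = copy.deepcopy(toy_limb.config)
        knee = config_m["joints"]["knee"]
        knee["condyle_medial_set"], knee["condyle_lateral_set"] = \
            knee["condyle_lateral_set"], knee["condyle_medial_set"]
        knee["plateau_medial_set"], knee["plateau_lateral_set"] = \
            knee["plateau_lateral_set"], knee["plateau_medial_set"]
        joints_m = build_joint_definitions(mirrored, config_m)
        pose = PoseParameters(values={"knee": 10.0})
        res = reconfigure_skeleton(toy_limb.model, limb_joints, pose)
        res_m = reconfigure_skeleton(mirrored, joints_m, pose)
        out = apply_skeleton_transforms(toy_limb.model, res)
        out_m = apply_skeleton_transforms(mirrored, res_m)
        nids = toy_limb.model.part_node_ids(2)[::15]
        expect = out.coords_of(nids) * np.array([1, -1, 1])
        assert np.abs(out_m.coords_of(nids) - expect).max() < 1e-6

    def test_cyclic_chain_rejected(self, toy_limb):
        config = copy.deepcopy(toy_limb.config)
        config["joints"]["knee"]["child_joints"] = ["hip"]
        joints = build_joint_definitions(toy_limb.model, config)
        with pytest.raises(ValidationError, match="cyclic"):
            reconfigure_skeleton(toy_limb.model, joints, PoseParameters())


class TestSpineChain:
    def test_spine_column_reconfiguration(self):
        col = make_spine_column(5)
        config = {"joints": {"lumbar": {
            "type": "spine",
            "vertebrae": col.config["vertebrae"],
            "driven_parts": [],
            "child_joints": []}}}
        joints = build_joint_definitions(col.model, config)
        res = reconfigure_skeleton(
            col.model, joints, PoseParameters(values={"lumbar": 25.0}))
        parts = [v["part"] for v in col.config["vertebrae"]]
        assert res.part_transforms[parts[-1]].rotation_angle() == \
            pytest.approx(25.0, abs=1e-9)
        assert res.part_transforms[parts[0]].rotation_angle() == \
            pytest.approx(5.0, abs=1e-9)
        # column stays articulated: neighbouring vertebra interfaces stay
        # within the disc spacing
        out = apply_skeleton_transforms(col.model, res)
        for a, b in zip(parts, parts[1:]):
            ca = out.coords_of(out.part_node_ids(a)).mean(axis=0)
            cb = out.coords_of(out.part_node_ids(b)).mean(axis=0)
            d = np.linalg.norm(ca - cb)
            assert 8.0 < d < 12.0  # ~height+disc, not disarticulated


def test_pose_json_roundtrip(tmp_path):
    import json

    path = tmp_path / "pose.json"
    path.write_text(json.dumps({"knee": 40.0, "hip": [10.0, 20.0, 30.0]}))
    pose = PoseParameters.from_json(path)
    assert pose.angle("knee") == 40.0
    assert np.allclose(pose.angle("hip"), [10, 20, 30])
    assert pose.angle("absent") == 0.0
    assert set(pose.posed_joints()) == {"knee", "hip"}
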