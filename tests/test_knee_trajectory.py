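import numpy as np
import pytest

from arthropose.errors import (
    DegenerateAxisError,
    NonPositiveCurvatureError,
    ValidationError,
)
from arthropose.geometry_core import PlateauPlane, curvature_tensor_field, rodrigues
from arthropose.knee_trajectory import (
    ContactState,
    HelicalAxis,
    Trajectory,
    compute_flexion_trajectory,
    find_contact_point,
    solve_helical_axis,
    step_flexion,
)

from conftest import icosphere


@pytest.fixture(scope="module")
def sphere_above_plane():
    """Sphere r=5 centered (0,0,10) over the plane z=0, with a pole vertex."""
    from arthropose.synthetic_fixtures import _ellipsoid_mesh

    mesh = _ellipsoid_mesh((0.0, 0.0, 10.0), (5.0, 5.0, 5.0), 0.4)
    field = curvature_tensor_field(mesh)
    return field


class TestFindContactPoint:
    def test_sphere_lowest_point(self, sphere_above_plane):
        plateau = PlateauPlane([0, 0, 0], [0, 0, 1])
        c = find_contact_point(sphere_above_plane, plateau)
        assert np.linalg.norm(c.point - [0, 0, 5]) < 1e-9
        assert np.linalg.norm(c.normal - [0, 0, -1]) < 1e-9

    def test_tilted_plane_support_point(self, sphere_above_plane):
        n = np.array([np.sin(np.radians(10)), 0.0, np.cos(np.radians(10))])
        plateau = PlateauPlane([0, 0, 0], n)
        c = find_contact_point(sphere_above_plane, plateau)
        expected = np.array([0, 0, 10.0]) - 5.0 * n  # closed-form support
        assert np.linalg.norm(c.point - expected) < 0.35  # mesh resolution

    def test_cylinder_matches_bruteforce(self, cylinder_knee):
        geom = cylinder_knee.geometry
        c = find_contact_point(geom.condyle_medial, geom.plateau_medial)
        mesh = geom.condyle_medial.mesh
        # brute force: same two-level objective over every face
        plateau = geom.plateau_medial
        best = None
        for fi in range(mesh.n_faces):
            vn = mesh.vertex_normals[mesh.faces[fi]]
            for bary in np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1],
                                  [1 / 3, 1 / 3, 1 / 3]]):
                nrm = bary @ vn
                nrm /= np.linalg.norm(nrm)
                mis = 1.0 + nrm @ plateau.normal
                if best is None or mis < best:
                    best = mis
        # refined point is at least as aligned as any coarse probe
        mis_found = 1.0 + c.normal @ plateau.normal
        assert mis_found <= best + 1e-9
        # and sits on the lowest generatrix
        assert abs(c.point[0]) < 0.2
        # interior contact sits a chord-sag (edge^2/8R ~ 0.006) off the
        # analytic generatrix
        assert abs(c.point[2]) < 0.01

    def test_penetration_warning(self, sphere_above_plane):
        plateau = PlateauPlane([0, 0, 6.0], [0, 0, 1])  # 1 mm penetration
        with pytest.warns(RuntimeWarning):
            find_contact_point(sphere_above_plane, plateau)

    def test_empty_mesh_error(self):
        from arthropose.surface import TriMesh
        from arthropose.geometry_core import CurvatureTensorField

        empty = CurvatureTensorField(
            mesh=TriMesh(np.zeros((0, 3)), np.zeros((0, 3), np.int64)),
            tensors=np.zeros((0, 3, 3)), areas=np.zeros(0),
            normals=np.zeros((0, 3)), reliable=np.zeros(0, bool))
        with pytest.raises(ValidationError):
            find_contact_point(empty, PlateauPlane([0, 0, 0], [0, 0, 1]))


class TestSolveHelicalAxis:
    def test_sphere_fixture_radii(self, sphere_knee):
        g = sphere_knee.geometry
        cm = find_contact_point(g.condyle_medial, g.plateau_medial)
        cl = find_contact_point(g.condyle_lateral, g.plateau_lateral)
        med, lat, axis = solve_helical_axis(cm, cl, g.condyle_medial,
                                            g.condyle_lateral)
        R = sphere_knee.truth["r_m"]
        assert med.radius == pytest.approx(R, rel=0.01)
        assert lat.radius == pytest.approx(R, rel=0.01)
        assert np.linalg.norm(
            med.intersection - sphere_knee.truth["center_medial"]) < 0.5
        assert np.linalg.norm(
            lat.intersection - sphere_knee.truth["center_lateral"]) < 0.5
        med.validate()
        lat.validate()

    def test_cylinder_hinge(self, cylinder_knee):
        g = cylinder_knee.geometry
        cm = find_contact_point(g.condyle_medial, g.plateau_medial)
        cl = find_contact_point(g.condyle_lateral, g.plateau_lateral)
        med, lat, axis = solve_helical_axis(cm, cl, g.condyle_medial,
                                            g.condyle_lateral)
        assert abs(axis.direction @ np.array([0, 1, 0.0])) > np.cos(
            np.radians(0.5))
        assert med.radius == pytest.approx(20.0, rel=0.01)

    def test_isotropic_tensor_one_iteration(self):
        kappa = 0.1
        C = kappa * np.diag([1.0, 1.0, 0.0])  # isotropic in the xy plane

        class FakeField:
            tensors = np.array([C])
            mesh = None

        med = ContactState("medial", np.array([0.0, -10, 0]),
                           np.array([0, 0, -1.0]))
        lat = ContactState("lateral", np.array([0.0, 10, 0]),
                           np.array([0, 0, -1.0]))

        class F:
            def __init__(self):
                self.tensors = np.array([C])

                class M:
                    vertices = np.zeros((1, 3))

                self.mesh = M()

        m, l, axis = solve_helical_axis(med, lat, F(), F())
        assert m.radius == pytest.approx(1.0 / kappa, abs=1e-9)
        assert l.radius == pytest.approx(1.0 / kappa, abs=1e-9)

    def test_flat_condyle_error(self):
        C = np.zeros((3, 3))

        class F:
            def __init__(self):
                self.tensors = np.array([C])

                class M:
                    vertices = np.zeros((1, 3))

                self.mesh = M()

        med = ContactState("medial", np.array([0.0, -10, 0]),
                           np.array([0, 0, -1.0]))
        lat = ContactState("lateral", np.array([0.0, 10, 0]),
                           np.array([0, 0, -1.0]))
        with pytest.raises(NonPositiveCurvatureError, match="medial"):
            solve_helical_axis(med, lat, F(), F())


class TestStepFlexion:
    def test_isometry_on_plateau(self, sphere_knee):
        g = sphere_knee.geometry
        axis = HelicalAxis([0, 1, 0], [0, -40, 20], [0, 40, 20])
        g2, T = step_flexion(g, axis, 0.5)
        pts = g.tibia_bodies[0].vertices
        d0 = np.linalg.norm(pts - np.array([0, -40, 20.0]), axis=1)
        d1 = np.linalg.norm(g2.tibia_bodies[0].vertices
                            - np.array([0, -40, 20.0]), axis=1)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_two_half_steps_equal_one(self, sphere_knee):
        g = sphere_knee.geometry
        axis = HelicalAxis([0, 1, 0], [0, -40, 20], [0, 40, 20])
        _, T1 = step_flexion(g, axis, 0.5)
        g_half, _ = step_flexion(g, axis, 0.5)
        # same fixed axis: composition equals a single 1.0 deg step
        _, T_full = step_flexion(g, axis, 1.0)
        composed = T1.compose(T1)
        assert np.abs(composed.matrix() - T_full.matrix()).max() < 1e-12

    def test_sphere_tangency_preserved(self, sphere_knee):
        g = sphere_knee.geometry
        center = sphere_knee.truth["center_medial"]
        axis = HelicalAxis([0, 1, 0], center, sphere_knee.truth["center_lateral"])
        g2, _ = step_flexion(g, axis, 2.0)
        d = g2.plateau_medial.signed_distance(center)
        assert abs(abs(d) - 20.0) < 1e-6 * 20.0

    def test_step_bounds(self, sphere_knee):
        axis = HelicalAxis([0, 1, 0], [0, -40, 20], [0, 40, 20])
        with pytest.raises(ValidationError):
            step_flexion(sphere_knee.geometry, axis, 0.0)
        with pytest.raises(ValidationError):
            step_flexion(sphere_knee.geometry, axis, 5.5)


class TestTrajectory:
    def test_step_count(self, sphere_knee):
        traj = compute_flexion_trajectory(sphere_knee.geometry, 4.0, step=0.5)
        assert len(traj.steps) == 8
        assert traj.cumulative_angle == pytest.approx(4.0, abs=1e-9)

    def test_truncated_last_step(self, sphere_knee):
        traj = compute_flexion_trajectory(sphere_knee.geometry, 1.3, step=0.5)
        assert [s.angle for s in traj.steps] == pytest.approx([0.5, 0.5, 0.3])

    def test_cumulative_invariants(self, sphere_knee):
        traj = compute_flexion_trajectory(sphere_knee.geometry, 3.0, step=0.5)
        T = traj.composed_transform
        manual = np.eye(4)
        for s in traj.steps:
            manual = s.transform.matrix() @ manual
        assert np.abs(T.matrix() - manual).max() < 1e-9

    def test_determinism(self, sphere_knee):
        t1 = compute_flexion_trajectory(sphere_knee.geometry, 2.0, step=0.5)
        t2 = compute_flexion_trajectory(sphere_knee.geometry, 2.0, step=0.5)
        for a, b in zip(t1.steps, t2.steps):
            assert np.array_equal(a.transform.matrix(), b.transform.matrix())

    def test_sphere_drift_small(self, sphere_knee):
        traj = compute_flexion_trajectory(sphere_knee.geometry, 10.0, step=0.5)
        ct = np.array([s.contact_medial_tibia for s in traj.steps])
        assert np.linalg.norm(ct[-1] - ct[0]) < 0.02 * 20.0

    def test_cylinder_hinge_limit(self, cylinder_knee):
        traj = compute_flexion_trajectory(cylinder_knee.geometry, 10.0,
                                          step=0.5)
        T = traj.composed_transform
        assert T.rotation_angle() == pytest.approx(10.0, abs=0.5)
        assert abs(T.rotation_axis() @ np.array([0, 1, 0.0])) > np.cos(
            np.radians(0.5))

    def test_tangency_invariant(self, sphere_knee):
        geom = sphere_knee.geometry
        traj = compute_flexion_trajectory(geom, 5.0, step=0.5)
        # replay and check the plateau stays within the tangency band
        cur = geom
        for s in traj.steps:
            cur = cur.transformed_tibia(s.transform)
            d = cur.plateau_medial.signed_distance(
                cur.condyle_medial.mesh.vertices).min()
            assert -0.05 <= d <= 0.5

    def test_inverted_returns_to_origin(self, sphere_knee):
        traj = compute_flexion_trajectory(sphere_knee.geometry, 5.0, step=0.5)
        T = traj.inverted().composed_transform.compose(
            traj.composed_transform)
        assert T.rotation_angle() < 1e-9
        assert np.abs(T.translation).max() < 1e-9

    def test_json_roundtrip(self, tmp_path, sphere_knee):
        traj = compute_flexion_trajectory(sphere_knee.geometry, 2.0, step=0.5)
        path = tmp_path / "traj.json"
        traj.to_json(path)
        back = Trajectory.from_json(path)
        assert len(back.steps) == len(traj.steps)
        assert np.abs(back.composed_transform.matrix()
                      - traj.composed_transform.matrix()).max() < 1e-12
        traj.to_csv(tmp_path / "traj.csv")
        assert (tmp_path / "traj.csv").read_text().count("\n") == \
            len(traj.steps) + 1

    def test_extension_negative_target(self, sphere_knee):
        traj = compute_flexion_trajectory(sphere_knee.geometry, -2.0,
                                          step=0.5)
        assert traj.cumulative_angle == pytest.approx(-2.0, abs=1e-9)

    def test_offset_hook_changes_axis(self, sphere_knee):
        base = compute_flexion_trajectory(sphere_knee.geometry, 1.0, step=0.5)

        def hook(step_index):
            return ((1.0, 0.0), (0.0, 0.0))

        shifted = compute_flexion_trajectory(sphere_knee.geometry, 1.0,
                                             step=0.5, offset_hook=hook)
        d = np.linalg.norm(base.steps[0].axis.point_medial
                           - shifted.steps[0].axis.point_medial)
        assert d == pytest.approx(1.0, abs=1e-6)


def test_degenerate_axis_error():
    C = 0.05 * np.diag([1.0, 1.0, 0.0])

    class F:
        def __init__(self):
            self.tensors = np.array([C])

            class M:
                vertices = np.zeros((1, 3))

            self.mesh = M()

    # coincident contact points -> degenerate
    med = ContactState("medial", np.zeros(3), np.array([0, 0, -1.0]))
    lat = ContactState("lateral", np.zeros(3), np.array([0, 0, -1.0]))
    with pytest.raises(DegenerateAxisError):
        solve_helical_axis(med, lat, F(), F())
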