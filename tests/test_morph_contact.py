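import numpy as np
import pytest

from arthropose.geometry_core import RigidTransform, rodrigues
from arthropose.morph_contact import (
    chamfer_distance,
    deform_soft_tissue,
    detect_penetrations,
    edge_length_cv,
    preliminary_morph,
    reduced_bone_landmarks,
    refine_interface,
    resolve_penetrations,
    segment_capsule,
)
from arthropose.proximity import signed_distance
from arthropose.surface import TriMesh

from conftest import icosphere


def inward_sphere(radius, subdiv=3):
    """Capsule-oriented sphere: outward normals face the enclosed joint."""
    m = icosphere(subdiv, radius)
    return TriMesh(m.vertices, m.faces[:, ::-1])


@pytest.fixture(scope="module")
def tube_scenario(tube_capsule):
    """Preliminary-morphed tube with real penetrations (tibia shifted)."""
    cap, fem, tib = (tube_capsule.capsule, tube_capsule.femur,
                     tube_capsule.tibia)
    seg = segment_capsule(cap, fem, tib)
    T_p = RigidTransform.identity()
    T_d = RigidTransform(np.eye(3), [4.0, 0.0, 2.0])
    base_f = signed_distance(cap, fem.vertices)[0]
    base_t = signed_distance(cap, tib.vertices)[0]
    sf, tf = reduced_bone_landmarks(fem, T_p, tib.vertices.mean(axis=0))
    st, tt = reduced_bone_landmarks(tib, T_d, fem.vertices.mean(axis=0))
    morphed = preliminary_morph(
        cap, (np.vstack([sf, st]), np.vstack([tf, tt])), seg, T_p, T_d)
    return dict(cap=cap, fem=fem, tib=tib, seg=seg, T_d=T_d,
                base_f=base_f, base_t=base_t, morphed=morphed,
                tib_moved=tib.transformed(T_d))


class TestSegmentCapsule:
    def test_tube_classification_matches_bruteforce(self, tube_capsule):
        cap, fem, tib = (tube_capsule.capsule, tube_capsule.femur,
                         tube_capsule.tibia)
        seg = segment_capsule(cap, fem, tib, tol=1.0)
        seg.validate(cap.n_vertices)
        # brute-force distance classification (exhaustive point-triangle)
        from arthropose.proximity import _closest_on_triangles

        def min_dist(bone, pts):
            tri = bone.vertices[bone.faces]
            out = np.empty(len(pts))
            for i, p in enumerate(pts):
                cp = _closest_on_triangles(p[None, :], tri)
                out[i] = np.sqrt(((cp - p) ** 2).sum(axis=1).min())
            return out

        df = min_dist(fem, cap.vertices)
        dt = min_dist(tib, cap.vertices)
        prox = set(np.nonzero(df <= 1.0)[0].tolist())
        dist = set(np.nonzero((dt <= 1.0) & (df > 1.0))[0].tolist())
        assert set(seg.proximal_nodes.tolist()) == prox
        assert set(seg.distal_nodes.tolist()) == dist
        # inner wall -> interior, outer wall -> exterior
        rho = np.hypot(cap.vertices[:, 0], cap.vertices[:, 1])
        inner = tube_capsule.truth["inner_radius"]
        outer = tube_capsule.truth["outer_radius"]
        for i in seg.interior_nodes:
            assert rho[i] < (inner + outer) / 2
        for i in seg.exterior_nodes:
            assert rho[i] > inner

    def test_zero_tol_no_attachment(self, tube_capsule):
        seg = segment_capsule(tube_capsule.capsule, tube_capsule.femur,
                              tube_capsule.tibia, tol=0.0)
        assert len(seg.proximal_nodes) == 0
        assert len(seg.distal_nodes) == 0
        seg.validate(tube_capsule.capsule.n_vertices)

    def test_node_order_invariance(self, tube_capsule):
        cap = tube_capsule.capsule
        perm = np.random.default_rng(0).permutation(cap.n_vertices)
        inv = np.argsort(perm)
        cap2 = TriMesh(cap.vertices[perm], inv[cap.faces])
        seg1 = segment_capsule(cap, tube_capsule.femur, tube_capsule.tibia)
        seg2 = segment_capsule(cap2, tube_capsule.femur, tube_capsule.tibia)
        assert set(inv[seg1.proximal_nodes].tolist()) == \
            set(seg2.proximal_nodes.tolist())
        assert set(inv[seg1.interior_nodes].tolist()) == \
            set(seg2.interior_nodes.tolist())


class TestPreliminaryMorph:
    def test_identity_transforms_no_motion(self, tube_capsule):
        cap, fem, tib = (tube_capsule.capsule, tube_capsule.femur,
                         tube_capsule.tibia)
        seg = segment_capsule(cap, fem, tib)
        I = RigidTransform.identity()
        sf, tf = reduced_bone_landmarks(fem, I, tib.vertices.mean(axis=0))
        st, tt = reduced_bone_landmarks(tib, I, fem.vertices.mean(axis=0))
        out = preliminary_morph(cap, (np.vstack([sf, st]),
                                      np.vstack([tf, tt])), seg, I, I)
        assert np.abs(out.vertices - cap.vertices).max() < 1e-8

    def test_whole_rigid_rotation_reproduced(self, tube_capsule):
        cap, fem, tib = (tube_capsule.capsule, tube_capsule.femur,
                         tube_capsule.tibia)
        seg = segment_capsule(cap, fem, tib)
        T = rodrigues([0, 0, 1], 25.0, [1, 2, 3])
        sf, tf = reduced_bone_landmarks(fem, T, tib.vertices.mean(axis=0))
        st, tt = reduced_bone_landmarks(tib, T, fem.vertices.mean(axis=0))
        out = preliminary_morph(cap, (np.vstack([sf, st]),
                                      np.vstack([tf, tt])), seg, T, T)
        assert np.abs(out.vertices - T.apply(cap.vertices)).max() < 1e-6

    def test_scenario_produces_penetrations(self, tube_scenario):
        s = tube_scenario
        rep_f = detect_penetrations(s["fem"], s["morphed"],
                                    baseline_signs=s["base_f"])
        rep_t = detect_penetrations(s["tib_moved"], s["morphed"],
                                    baseline_signs=s["base_t"])
        assert len(rep_f) + len(rep_t) >= 1


class TestDetectPenetrations:
    def test_contained_bone_clean(self):
        capsule = inward_sphere(1.0)
        bone = icosphere(2, 0.8)
        rep = detect_penetrations(bone, capsule)
        assert rep.is_empty

    def test_protruding_bone_matches_bruteforce(self):
        capsule = inward_sphere(1.0, subdiv=3)
        bone = icosphere(2, 1.2)
        rep = detect_penetrations(bone, capsule)
        expected = set(np.nonzero(
            np.linalg.norm(bone.vertices, axis=1) > 1.0)[0].tolist())
        assert set(rep.penetrating_nodes.tolist()) == expected
        assert np.allclose(-rep.signed_depths, 0.2, atol=0.02)

    def test_grazing_is_clean(self):
        capsule = inward_sphere(1.0, subdiv=3)
        # bone vertices exactly on the capsule vertices: depth < 1e-6
        bone = icosphere(3, 1.0)
        rep = detect_penetrations(bone, capsule)
        assert rep.is_empty

    def test_orientation_flip_filter(self):
        capsule = inward_sphere(1.0)
        bone = icosphere(2, 1.2)
        # baseline claims the protruding nodes were already negative:
        baseline = -np.ones(bone.n_vertices)
        rep = detect_penetrations(bone, capsule, baseline_signs=baseline)
        assert rep.is_empty

    def test_csv_export(self, tmp_path):
        capsule = inward_sphere(1.0)
        bone = icosphere(1, 1.2)
        rep = detect_penetrations(bone, capsule)
        path = tmp_path / "pen.csv"
        rep.export_csv(path)
        assert path.read_text().startswith("node,depth_mm,nearest_face")


class TestResolvePenetrations:
    def test_sphere_overlap_resolved(self):
        capsule = inward_sphere(1.0, subdiv=3)
        bone = icosphere(2, 1.2)
        rep = detect_penetrations(bone, capsule)
        out = resolve_penetrations(capsule, rep)
        assert detect_penetrations(bone, out).is_empty
        disp = np.linalg.norm(out.vertices - capsule.vertices, axis=1)
        # moved vertices clear the bone by roughly depth + clearance
        assert disp.max() < (0.2 + 0.1) * 1.6

    def test_empty_report_unchanged(self):
        capsule = inward_sphere(1.0)
        bone = icosphere(2, 0.5)
        rep = detect_penetrations(bone, capsule)
        out = resolve_penetrations(capsule, rep)
        assert out is capsule

    def test_idempotent_on_clean(self):
        capsule = inward_sphere(1.0)
        bone = icosphere(2, 0.5)
        out = resolve_penetrations(
            capsule, detect_penetrations(bone, capsule))
        out2 = resolve_penetrations(out, detect_penetrations(bone, out))
        assert np.array_equal(out.vertices, out2.vertices)

    def test_tube_scenario_resolves(self, tube_scenario):
        s = tube_scenario
        cur = s["morphed"]
        for _ in range(4):
            moved = False
            for bone, base in ((s["fem"], s["base_f"]),
                               (s["tib_moved"], s["base_t"])):
                rep = detect_penetrations(bone, cur, baseline_signs=base)
                if not rep.is_empty:
                    cur = resolve_penetrations(cur, rep,
                                               fixed=s["seg"].fixed_nodes)
                    moved = True
            if not moved:
                break
        assert detect_penetrations(s["fem"], cur,
                                   baseline_signs=s["base_f"]).is_empty
        assert detect_penetrations(s["tib_moved"], cur,
                                   baseline_signs=s["base_t"]).is_empty
        # attached segments never moved
        fixed = s["seg"].fixed_nodes
        assert np.abs(cur.vertices[fixed]
                      - s["morphed"].vertices[fixed]).max() == 0.0


class TestRefineInterface:
    def test_near_fixed_point_on_smooth(self, tube_capsule):
        cap = tube_capsule.capsule
        seg = segment_capsule(cap, tube_capsule.femur, tube_capsule.tibia)
        out = refine_interface(cap, cap, fixed=seg.fixed_nodes)
        disp = np.linalg.norm(out.vertices - cap.vertices, axis=1)
        assert disp.max() < 0.05

    def test_oscillation_recovery(self, tube_capsule):
        # spec example: alternate nodes perturbed +/-0.3 mm along normals;
        # with the smooth surface as reference the oscillation is removed.
        # NOTE: the plain edge-length CV only drops ~18% here, not the 50%
        # the spec example guessed: normal-direction oscillation stretches
        # most edges nearly equally (adds little length *variance*), and the
        # revolved tube has an irreducible CV floor from its radius spread.
        # Asserted instead: CV strictly reduced toward the baseline and the
        # oscillation amplitude itself removed (Chamfer to smooth < 0.05).
        cap = tube_capsule.capsule
        seg = segment_capsule(cap, tube_capsule.femur, tube_capsule.tibia)
        free = np.ones(cap.n_vertices, bool)
        free[seg.fixed_nodes] = False
        sgn = np.where(np.arange(cap.n_vertices) % 2 == 0, 1.0, -1.0)
        verts = cap.vertices + (0.3 * sgn * free)[:, None] * cap.vertex_normals
        perturbed = cap.with_vertices(verts)
        out = refine_interface(perturbed, cap, fixed=seg.fixed_nodes)
        cv_p = edge_length_cv(perturbed)
        cv_o = edge_length_cv(out)
        cv_base = edge_length_cv(cap)
        assert cv_o < cv_p
        assert cv_o < cv_base + 0.02
        assert chamfer_distance(out, cap) < 0.05
        # fixed nodes untouched
        assert np.abs(out.vertices[seg.fixed_nodes]
                      - perturbed.vertices[seg.fixed_nodes]).max() == 0.0

    def test_penetration_freedom_preserved(self, tube_scenario):
        s = tube_scenario
        cur = s["morphed"]
        for bone, base in ((s["fem"], s["base_f"]),
                           (s["tib_moved"], s["base_t"])):
            rep = detect_penetrations(bone, cur, baseline_signs=base)
            if not rep.is_empty:
                cur = resolve_penetrations(cur, rep,
                                           fixed=s["seg"].fixed_nodes)
        refined = refine_interface(cur, cur, fixed=s["seg"].fixed_nodes)
        assert detect_penetrations(s["fem"], refined,
                                   baseline_signs=s["base_f"]).is_empty
        assert detect_penetrations(s["tib_moved"], refined,
                                   baseline_signs=s["base_t"]).is_empty
        assert chamfer_distance(refined, cur) < 0.2


class TestDeformSoftTissue:
    def _flesh_model(self):
        from arthropose.fe_model_io import FEModel

        m = FEModel()
        m.parts[4] = "flesh"
        k = 1
        grid = {}
        for z in range(3):
            for y in range(3):
                for x in range(3):
                    grid[(x, y, z)] = k
                    m.nodes[k] = np.array([x, y, z], float) * 5.0
                    k += 1
        eid = 1
        for z in range(2):
            for y in range(2):
                for x in range(2):
                    m.solids[eid] = (4, (
                        grid[(x, y, z)], grid[(x + 1, y, z)],
                        grid[(x + 1, y + 1, z)], grid[(x, y + 1, z)],
                        grid[(x, y, z + 1)], grid[(x + 1, y, z + 1)],
                        grid[(x + 1, y + 1, z + 1)], grid[(x, y + 1, z + 1)]))
                    eid += 1
        return m

    def test_identity_landmarks(self):
        m = self._flesh_model()
        rng = np.random.default_rng(0)
        src = rng.uniform(-5, 15, size=(12, 3))
        out = deform_soft_tissue(m, (src, src), [4])
        for nid in m.nodes:
            assert np.abs(out.nodes[nid] - m.nodes[nid]).max() < 1e-8

    def test_rigid_motion_landmarks(self):
        m = self._flesh_model()
        T = rodrigues([1, 0, 1], 30.0, [5, 5, 5])
        rng = np.random.default_rng(1)
        src = rng.uniform(-5, 15, size=(16, 3))
        out = deform_soft_tissue(m, (src, T.apply(src)), [4])
        for nid in m.nodes:
            assert np.abs(out.nodes[nid] - T.apply(m.nodes[nid])).max() < 1e-6

    def test_exact_targets_override(self):
        m = self._flesh_model()
        rng = np.random.default_rng(2)
        src = rng.uniform(-5, 15, size=(10, 3))
        target = {1: np.array([99.0, 0.0, 0.0])}
        out = deform_soft_tissue(m, (src, src + 1.0), [4],
                                 exact_targets=target)
        assert np.array_equal(out.nodes[1], [99.0, 0.0, 0.0])
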