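import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from craniowrap.grids import BinaryMask, VoxelGrid
from craniowrap.metrics import (check_topology, overlap_metrics,
                                surface_distance, voxelize)
from craniowrap.quality import (INTERNAL_STRUCTURES, SUPERFICIAL_LANDMARKS,
                                QualityReport, aggregate_visibility,
                                emit_quality_report, read_quality_report)


def _mask(data):
    return BinaryMask(data=np.asarray(data))


class TestOverlapMetrics:
    def test_identity_is_perfect(self):
        m = _mask(np.random.default_rng(0).random((6, 6, 6)) > 0.5)
        assert overlap_metrics(m, m) == (1.0, 1.0, 1.0)

    def test_disjoint_is_zero(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert overlap_metrics(_mask(a), _mask(b)) == (0.0, 0.0, 0.0)

    def test_hand_computed_contingency(self):
        # |P| = 4, |T| = 4, |P n T| = 2 -> all three equal 0.5
        p = np.zeros((4, 4, 4))
        t = np.zeros((4, 4, 4))
        p.ravel()[:4] = 1
        t.ravel()[2:6] = 1
        assert overlap_metrics(_mask(p), _mask(t)) == (0.5, 0.5, 0.5)

    def test_empty_masks_are_nan_with_warning(self):
        e = _mask(np.zeros((3, 3, 3)))
        with pytest.warns(UserWarning):
            d, r, p = overlap_metrics(e, e)
        assert np.isnan(d) and np.isnan(r) and np.isnan(p)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            overlap_metrics(_mask(np.zeros((3, 3, 3))),
                            _mask(np.zeros((4, 4, 4))))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 27 - 1), st.integers(0, 2 ** 27 - 1))
    def test_dice_is_harmonic_mean_of_recall_precision(self, seed_a, seed_b):
        rng_a = np.random.default_rng(seed_a)
        rng_b = np.random.default_rng(seed_b)
        p = rng_a.random((5, 5, 5)) > 0.5
        t = rng_b.random((5, 5, 5)) > 0.5
        if not p.any() or not t.any():
            return
        d, r, pr = overlap_metrics(_mask(p), _mask(t))
        assert 0.0 <= d <= 1.0
        if r + pr > 0:
            assert d == pytest.approx(2 * r * pr / (r + pr))
        else:
            assert d == 0.0
        assert (d == 1.0) == np.array_equal(p, t)


class TestVoxelize:
    def test_icosphere_volume_analytic(self):
        tmpl = VoxelGrid(data=np.zeros((48, 48, 48), np.float32),
                         spacing=(1, 1, 1), origin=(-23.5, -23.5, -23.5))
        ico = trimesh.creation.icosphere(3, radius=20.0)
        count = voxelize(ico, tmpl).data.sum()
        assert count == pytest.approx(4 / 3 * np.pi * 20 ** 3, rel=0.02)

    def test_mesh_outside_template_is_empty(self):
        tmpl = VoxelGrid(data=np.zeros((10, 10, 10), np.float32))
        ico = trimesh.creation.icosphere(2, radius=2.0)
        ico.apply_translation([100, 100, 100])
        assert voxelize(ico, tmpl).data.sum() == 0

    def test_non_watertight_rejected(self):
        ico = trimesh.creation.icosphere(1, radius=5.0)
        broken = trimesh.Trimesh(ico.vertices, ico.faces[:-1], process=False)
        tmpl = VoxelGrid(data=np.zeros((12, 12, 12), np.float32))
        with pytest.raises(ValueError):
            voxelize(broken, tmpl)

    def test_round_trip_against_ball_mask(self, ball_mask):
        from craniowrap.surface import WrapConfig, extract_surface
        mask, _, _ = ball_mask
        mesh = extract_surface(mask, WrapConfig(
            step_size=0.5, max_iters=150, edge_length_bounds=(1.0, 2.5)),
            subdivisions=3)
        pred = voxelize(mesh, mask)
        d, _, _ = overlap_metrics(pred, mask)
        assert d >= 0.98


class TestSurfaceDistance:
    def test_self_distance_zero(self):
        ico = trimesh.creation.icosphere(2, radius=10.0)
        m, p95, mx = surface_distance(ico, ico, n_samples=2000)
        assert mx < 1e-9

    def test_concentric_spheres_offset(self):
        a = trimesh.creation.icosphere(3, radius=10.0)
        b = trimesh.creation.icosphere(3, radius=12.0)
        mean, _, _ = surface_distance(a, b, n_samples=4000)
        assert mean == pytest.approx(2.0, abs=0.15)

    def test_symmetric_in_arguments(self):
        a = trimesh.creation.icosphere(2, radius=10.0)
        b = trimesh.creation.icosphere(2, radius=11.5)
        d1 = surface_distance(a, b, n_samples=3000, seed=5)
        d2 = surface_distance(b, a, n_samples=3000, seed=5)
        assert d1[0] == pytest.approx(d2[0], rel=0.1)


class TestTopology:
    def test_icosphere_clean(self):
        rep = check_topology(trimesh.creation.icosphere(2, radius=5.0))
        assert rep.euler_characteristic == 2
        assert rep.watertight
        assert rep.n_self_intersections == 0
        assert rep.n_degenerate_faces == 0
        # independent half-edge identity: E = 3F/2 for closed triangle mesh
        assert rep.n_edges == 3 * rep.n_faces // 2

    def test_missing_face_breaks_watertightness(self):
        ico = trimesh.creation.icosphere(1, radius=5.0)
        broken = trimesh.Trimesh(ico.vertices, ico.faces[:-1], process=False)
        rep = check_topology(broken)
        assert not rep.watertight
        assert rep.n_boundary_edges == 3
        assert rep.euler_characteristic == 1

    def test_torus_euler_zero(self):
        rep = check_topology(trimesh.creation.torus(major_radius=10.0,
                                                    minor_radius=3.0),
                             count_intersections=False)
        assert rep.euler_characteristic == 0
        assert rep.watertight

    def test_crossing_triangles_detected(self):
        V = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0],
                      [0.5, 0.5, -1], [1.5, 0.5, 1], [0.5, 1.5, 1]], float)
        F = np.array([[0, 1, 2], [3, 4, 5]])
        mesh = trimesh.Trimesh(V, F, process=False)
        from craniowrap.metrics import count_self_intersections
        assert count_self_intersections(mesh) == 1


class TestQualityReport:
    def _report(self, case="c1", visible=5):
        lm = {k: i < visible for i, k in enumerate(SUPERFICIAL_LANDMARKS)}
        st_ = {k: True for k in INTERNAL_STRUCTURES}
        return QualityReport(case_id=case, stage="refined_model",
                             overall_quality=3, landmark_visibility=lm,
                             internal_structures=st_)

    def test_round_trip(self, tmp_path):
        r = self._report()
        p = tmp_path / "r.json"
        emit_quality_report(r, p)
        back = read_quality_report(p)
        assert back.landmark_visibility == r.landmark_visibility
        assert back.overall_quality == 3

    def test_wrong_landmark_count_rejected(self):
        lm = {f"l{i}": True for i in range(22)}
        with pytest.raises(ValueError, match="23"):
            QualityReport(case_id="x", stage="svr", overall_quality=2,
                          landmark_visibility=lm)

    def test_quality_scale_bounds(self):
        with pytest.raises(ValueError):
            QualityReport(case_id="x", stage="svr", overall_quality=5)
        with pytest.raises(ValueError):
            QualityReport(case_id="x", stage="nope", overall_quality=2)

    def test_aggregation_percentages(self):
        name = SUPERFICIAL_LANDMARKS[0]
        reports = [self._report(case=f"c{i}", visible=1 if i < 7 else 0)
                   for i in range(10)]
        agg = aggregate_visibility(reports)
        assert agg[name] == pytest.approx(70.0)
        assert len(agg) == 23
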