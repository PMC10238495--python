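"""Contour tracing, curvature series and persistence-length estimation."""

import numpy as np
import pytest

from ridgemetrics import geometry, synthetic
from ridgemetrics.geometry import KB


class TestTraceBranches:
    def test_straight_line_traced_in_order(self):
        mask = np.zeros((10, 30), dtype=bool)
        mask[5, 5:25] = True
        traces, n_loops = geometry.trace_branches(mask, dx=1.0, dy=1.0)
        assert n_loops == 0
        assert len(traces) == 1
        coords = traces[0].coords
        assert len(coords) == 20
        assert np.allclose(coords[:, 1], 5.0)
        assert np.array_equal(np.sort(coords[:, 0]), coords[:, 0])

    def test_plus_sign_splits_into_four_arms(self):
        mask = np.zeros((41, 41), dtype=bool)
        mask[20, 5:36] = True
        mask[5:36, 20] = True
        # 14-px arms survive the 10-point floor after branch-point removal
        traces, _ = geometry.trace_branches(mask, 1.0, 1.0)
        assert len(traces) == 4

    def test_plus_sign_short_arms_excluded(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[10, 2:19] = True
        mask[2:19, 10] = True
        # ~8-px arms fall below the 10-coordinate-point minimum
        traces, _ = geometry.trace_branches(mask, 1.0, 1.0)
        assert traces == []

    def test_loop_skipped_and_counted(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5] = mask[5:15, 14] = True
        mask[5, 5:15] = mask[14, 5:15] = True
        traces, n_loops = geometry.trace_branches(mask, 1.0, 1.0)
        assert traces == []
        assert n_loops == 1

    def test_curved_arc_retraced_endpoint_to_endpoint(self):
        # rasterize a gentle sine arc, retrace, check ordering is monotone
        x = np.arange(5, 60)
        y = np.round(20 + 6 * np.sin(x / 12.0)).astype(int)
        mask = np.zeros((40, 70), dtype=bool)
        mask[y, x] = True
        traces, _ = geometry.trace_branches(mask, 1.0, 1.0)
        assert len(traces) == 1
        xs = traces[0].coords[:, 0]
        assert abs(xs[0] - xs[-1]) >= 50   # spans endpoint to endpoint
        assert np.all(np.diff(xs) >= 0) or np.all(np.diff(xs) <= 0)


class TestOrientAndSmooth:
    def test_straight_line_is_fixed_point(self):
        t = np.arange(20, dtype=float)
        coords = np.column_stack([t * 0.6 + 1, t * 0.8 - 2])
        trace = geometry.ContourTrace(coords)
        out = geometry.orient_and_smooth(trace)
        assert np.allclose(out, coords, atol=1e-9)

    def test_smoothing_reduces_standardized_distance_noise(self):
        rng = np.random.default_rng(0)
        t = np.arange(30, dtype=float)
        coords = np.column_stack([t, np.sin(t / 5)]) + rng.normal(0, 0.05, (30, 2))
        out = geometry.orient_and_smooth(geometry.ContourTrace(coords))
        # smoothed curve is less wiggly: smaller mean squared second difference
        def rough(c):
            return np.mean(np.diff(c, 2, axis=0) ** 2)
        assert rough(out) < rough(coords)

    def test_rotation_matrix_convention(self):
        theta = np.pi / 2
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        assert np.allclose(R @ [1, 0], [0, 1], atol=1e-12)


class TestSplineInterpolate:
    def test_collinear_points_stay_collinear(self):
        t = np.arange(10, dtype=float)
        coords = np.column_stack([t, 2 * t + 1])
        dense = geometry.spline_interpolate(coords, factor=7)
        assert np.allclose(dense[:, 1], 2 * dense[:, 0] + 1, atol=1e-9)

    def test_passes_through_input_points(self):
        rng = np.random.default_rng(2)
        coords = np.cumsum(rng.normal(0, 1, (12, 2)), axis=0)
        dense = geometry.spline_interpolate(coords, factor=5)
        for p in coords:
            assert np.min(np.linalg.norm(dense - p, axis=1)) < 1e-9

    def test_circle_radial_deviation_small(self):
        ang = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        coords = 5.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        dense = geometry.spline_interpolate(coords, factor=10)
        r = np.linalg.norm(dense, axis=1)
        assert np.max(np.abs(r - 5.0)) < 0.01

    def test_duplicate_points_deduplicated(self):
        coords = np.array([[0, 0], [0, 0], [1, 1], [2, 0], [3, 1], [3, 1]], float)
        dense = geometry.spline_interpolate(coords, factor=3)
        assert np.all(np.isfinite(dense))


class TestCurvatureSeries:
    def test_collinear_zero_curvature(self):
        t = np.arange(15, dtype=float)
        cs = geometry.curvature_series(np.column_stack([t, -3 * t]))
        assert np.allclose(cs.kappa, 0, atol=1e-12)
        assert np.allclose(cs.kappa_s, 0, atol=1e-12)

    def test_circle_curvature_is_inverse_radius(self):
        ang = np.deg2rad(np.arange(0, 120))
        coords = 2.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        cs = geometry.curvature_series(coords)
        assert np.allclose(np.abs(cs.kappa), 0.5, rtol=1e-3)

    def test_arc_length_sum(self):
        t = np.arange(11, dtype=float) * 0.5
        cs = geometry.curvature_series(np.column_stack([t, np.zeros(11)]))
        assert cs.arc_length == pytest.approx(5.0)

    def test_series_lengths(self):
        rng = np.random.default_rng(1)
        coords = np.cumsum(rng.normal(0, 1, (20, 2)), axis=0)
        cs = geometry.curvature_series(coords)
        assert len(cs.theta) == 19
        assert len(cs.phi) == len(cs.theta) - 1
        assert len(cs.kappa) == len(cs.phi)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        coords = np.cumsum(rng.normal(0, 1, (25, 2)), axis=0)
        theta = 1.234
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        a = geometry.curvature_series(coords)
        b = geometry.curvature_series(coords @ R.T)
        assert np.allclose(a.kappa, b.kappa, atol=1e-9)
        assert np.allclose(a.kappa_s, b.kappa_s, atol=1e-9)

    def test_rescaled_curvature_consistency(self):
        # kappa_s = kappa * sqrt(ds_{k-1} + ds_k) per sample
        rng = np.random.default_rng(4)
        coords = np.cumsum(rng.normal(0, 1, (20, 2)), axis=0)
        cs = geometry.curvature_series(coords)
        pair = cs.ds[:-1] + cs.ds[1:]
        assert np.allclose(cs.kappa_s, cs.kappa * np.sqrt(pair), atol=1e-12)

    def test_zero_length_segment_rejected(self):
        with pytest.raises(ValueError):
            geometry.curvature_series(np.array([[0, 0], [0, 0], [1, 1]], float))


class TestFitLp:
    def test_exact_gaussian_gives_lp_two_over_variance(self):
        rng = np.random.default_rng(5)
        ks = rng.normal(0, np.sqrt(2.0), 200000)
        est = geometry.fit_lp(ks)
        assert est.lp_moment == pytest.approx(1.0, rel=3 / np.sqrt(len(ks)) * 3)
        assert est.lp == pytest.approx(1.0, rel=0.05)

    def test_flexural_rigidity_from_lp(self):
        rng = np.random.default_rng(6)
        ks = rng.normal(0, np.sqrt(2.0 / 6.1), 150000)
        est = geometry.fit_lp(ks, temperature=300.0)
        assert est.lp == pytest.approx(6.1, rel=0.05)
        assert est.ei == pytest.approx(est.lp * 1e-6 * KB * 300.0)
        assert est.ei == pytest.approx(2.5e-26, rel=0.1)

    def test_small_sample_warns(self):
        rng = np.random.default_rng(7)
        with pytest.warns(UserWarning, match="samples"):
            geometry.fit_lp(rng.normal(0, 1, 50))


class TestCriticalForce:
    def test_length_scaling(self):
        f1 = geometry.critical_force(6.1, 1.0)
        f2 = geometry.critical_force(6.1, 2.0)
        assert f1 / f2 == pytest.approx(4.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            geometry.critical_force(-1.0, 1.0)


class TestEndToEndRecovery:
    def test_wlc_chain_curvature_recovers_lp(self):
        chains = synthetic.make_wormlike_chains(6.0, 0.1, 501, 40, seed=10)
        ks = np.concatenate([geometry.curvature_series(c).kappa_s
                             for c in chains.chains])
        est = geometry.fit_lp(ks)
        assert est.lp == pytest.approx(6.0, rel=0.1)
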