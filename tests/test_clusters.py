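"""Ridge tracking, axis projection profiles and Gaussian curvature."""

import numpy as np
import pytest

from ridgemetrics import clusters, flow
from ridgemetrics.clusters import RidgeComponent
from ridgemetrics.grid import PixelGrid


def line_component(n=10, angle=0.0, bright_at=None):
    t = np.arange(n, dtype=float)
    coords = np.column_stack([t * np.cos(angle), t * np.sin(angle)])
    I = np.ones(n)
    if bright_at is not None:
        I[bright_at] = 10.0
    return RidgeComponent(coords, I, tuple(coords.mean(axis=0)))


class TestTrackRidges:
    def test_stationary_identity_assignment(self):
        comps = [line_component(), line_component(angle=0.1)]
        per_frame = [comps, comps, comps]
        tracks = clusters.track_ridges(per_frame, cutoff=2.3)
        assert len(tracks) == 2
        assert all(len(t) == 3 for t in tracks)

    def test_lap_keeps_identities_over_swap(self):
        # cost matrix [[1, 4], [4, 1]]: staying beats swapping
        a = [RidgeComponent([[0, 0]], [1], (0.0, 0.0)),
             RidgeComponent([[5, 0]], [1], (5.0, 0.0))]
        b = [RidgeComponent([[1, 0]], [1], (1.0, 0.0)),
             RidgeComponent([[6, 0]], [1], (6.0, 0.0))]
        tracks = clusters.track_ridges([a, b], cutoff=2.3)
        assert len(tracks) == 2
        for tr in tracks:
            (t0, c0), (t1, c1) = tr.samples
            assert abs(c1.centroid[0] - c0.centroid[0]) == pytest.approx(1.0)

    def test_large_jump_starts_new_track(self):
        a = [RidgeComponent([[0, 0]], [1], (0.0, 0.0))]
        b = [RidgeComponent([[3, 0]], [1], (3.0, 0.0))]
        tracks = clusters.track_ridges([a, b], cutoff=2.3)
        assert len(tracks) == 2


class TestRidgeAxis:
    def test_horizontal_line(self):
        e1, e2, iso = clusters.ridge_axis(line_component())
        assert (e1, e2) == pytest.approx((1.0, 0.0), abs=1e-12)
        assert not iso

    def test_diagonal_line(self):
        e1, e2, _ = clusters.ridge_axis(line_component(angle=np.pi / 4))
        assert (e1, e2) == pytest.approx((np.sqrt(2) / 2, np.sqrt(2) / 2))

    def test_rotation_equivariance_mod_sign(self):
        comp = line_component(n=14, angle=0.3)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        rotated = RidgeComponent(comp.coords @ R.T, comp.intensities,
                                 tuple((R @ np.array(comp.centroid))))
        e = np.array(clusters.ridge_axis(comp)[:2])
        er = np.array(clusters.ridge_axis(rotated)[:2])
        assert min(np.linalg.norm(er - R @ e), np.linalg.norm(er + R @ e)) < 1e-9

    def test_isotropic_component_flagged(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        comp = RidgeComponent(coords, np.ones(4), (0.5, 0.5))
        _, _, iso = clusters.ridge_axis(comp)
        assert iso


class TestIntensityProfile:
    def test_bright_pixel_at_expected_bin(self):
        comp = line_component(n=12, bright_at=7)
        prof = clusters.intensity_profile(comp)
        assert np.argmax(prof.I_p) == 7

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        t = np.arange(20, dtype=float)
        coords = np.column_stack([t, 0.3 * t])
        comp = RidgeComponent(coords, rng.random(20), tuple(coords.mean(axis=0)))
        prof = clusters.intensity_profile(comp)
        assert prof.I_p.sum() == pytest.approx(comp.intensities.sum())
        assert np.hypot(prof.e1, prof.e2) == pytest.approx(1.0)

    def test_rotated_copy_same_profile_shape(self):
        comp = line_component(n=15, bright_at=4)
        theta = np.deg2rad(30)
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        rot = RidgeComponent(comp.coords @ R.T, comp.intensities,
                             tuple(R @ np.array(comp.centroid)))
        p0 = clusters.intensity_profile(comp, pitch=1.0)
        p1 = clusters.intensity_profile(rot, pitch=1.0)
        # peak position relative to the profile start agrees within one bin
        off0 = np.argmax(p0.I_p)
        off1 = np.argmax(p1.I_p)
        assert min(abs(off1 - off0), abs((len(p1.I_p) - 1 - off1) - off0)) <= 1


class TestComponentsFromMask:
    def test_two_blobs_found_with_weighted_centroids(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 2:8] = True
        mask[15, 10:18] = True
        img = np.ones((20, 20))
        comps = clusters.components_from_mask(mask, img, dx=0.5, dy=0.5)
        assert len(comps) == 2
        assert comps[0].centroid[1] == pytest.approx(5 * 0.5)


class TestGaussianCurvature:
    def test_plane_zero_curvature(self):
        y, x = np.mgrid[:80, :80] * 0.1
        z = 0.3 + 0.2 * x
        cm = clusters.gaussian_curvature(PixelGrid(z, 0.1, 0.1), sigma=0.2)
        # interior only: replicate padding flattens the ramp at the border
        assert np.allclose(cm.K.values[20:-20, 20:-20], 0.0, atol=1e-9)
        assert np.all(cm.E * cm.G - cm.F ** 2 >= 1.0 - 1e-12)

    def test_saddle_curvature_at_center(self):
        n = 81
        c = (np.arange(n) - n // 2) * 0.05
        X, Y = np.meshgrid(c, c)
        cm = clusters.gaussian_curvature(PixelGrid(X * Y, 0.05, 0.05),
                                         sigma=0.25)
        # Monge K = -1/(1 + x^2 + y^2)^2 -> -1 at the origin
        assert cm.K.values[n // 2, n // 2] == pytest.approx(-1.0, rel=0.02)

    def test_hemisphere_central_curvature(self):
        R = 10.0
        c = (np.arange(81) - 40) * 0.1
        X, Y = np.meshgrid(c, c)
        z = np.sqrt(R ** 2 - X ** 2 - Y ** 2)
        cm = clusters.gaussian_curvature(PixelGrid(z, 0.1, 0.1), sigma=0.3)
        center = cm.K.values[30:50, 30:50]
        assert np.allclose(center, 1 / R ** 2, rtol=0.1)

    def test_translation_invariance_of_sign(self):
        rng = np.random.default_rng(1)
        from scipy.ndimage import gaussian_filter
        z = gaussian_filter(rng.random((64, 64)), 2)
        k0 = clusters.gaussian_curvature(PixelGrid(z, 0.1, 0.1), sigma=0.3)
        k1 = clusters.gaussian_curvature(PixelGrid(z + 5.0, 0.1, 0.1), sigma=0.3)
        assert np.allclose(k0.K.values, k1.K.values, atol=1e-9)


class TestCoincidenceAnalysis:
    def test_identical_sets_full_overlap(self):
        K = np.zeros((10, 10)); K[2:5, 2:5] = 10.0
        D = np.zeros((10, 10)); D[2:5, 2:5] = 1.0
        out = clusters.coincidence_analysis([K], [D], k_threshold=5.0,
                                            div_threshold=0.12)
        assert out["totals"]["pK_pD"] == 9
        assert out["totals"]["pK_nD"] == 0
        assert out["frames"][0]["frac_positive_K"] == 1.0

    def test_disjoint_sets_zero_overlap(self):
        K = np.zeros((10, 10)); K[0, 0] = 10.0
        D = np.zeros((10, 10)); D[9, 9] = 1.0
        out = clusters.coincidence_analysis([K], [D])
        assert sum(out["totals"].values()) == 0

    def test_clusters_at_sources_coincide_with_positive_divergence(self):
        # bright blobs (high +K of the intensity surface) placed at the
        # analytic sources of a divergent flow: +K/+D overlap beats +K/-D
        n = 64
        c = (np.arange(n) - n / 2 + 0.5) * 0.1
        X, Y = np.meshgrid(c, c)
        centers = [(-1.5, -1.5), (1.5, 1.5), (-1.5, 1.5)]
        z = sum(np.exp(-((X - a) ** 2 + (Y - b) ** 2) / 0.05)
                for a, b in centers)
        K = clusters.gaussian_curvature(PixelGrid(z, 0.1, 0.1), sigma=0.2)
        D = np.full((n, n), -0.2)
        for a, b in centers:
            D[np.hypot(X - a, Y - b) < 0.4] = 0.5
        out = clusters.coincidence_analysis([K.K.values], [D], k_threshold=5.0)
        assert out["totals"]["pK_pD"] > out["totals"]["pK_nD"]

    def test_misaligned_shapes_rejected(self):
        with pytest.raises(ValueError):
            clusters.coincidence_analysis([np.zeros((4, 4))], [np.zeros((5, 5))])
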