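"""Optic flow, divergence, strain-rate tensor and its decomposition."""

import numpy as np
import pytest

from ridgemetrics import flow, synthetic
from ridgemetrics.grid import PixelGrid


def affine_velocity_field(kind, c=0.1, n=32, psz=0.2):
    x = (np.arange(n) - (n - 1) / 2) * psz
    X, Y = np.meshgrid(x, x)
    fields = {
        "source": (c * X, c * Y),
        "shear": (c * Y, np.zeros_like(X)),
        "rotation": (c * Y, -c * X),
        "translation": (np.full_like(X, c), np.zeros_like(X)),
    }
    vx, vy = fields[kind]
    return flow.VelocityField(PixelGrid(vx, psz, psz), PixelGrid(vy, psz, psz), 1.0)


class TestOpticFlow:
    def test_identical_frames_zero_field(self):
        img = PixelGrid(np.random.default_rng(0).random((32, 32)))
        vel = flow.optic_flow(img, img, dt=0.5)
        assert np.allclose(vel.vx.values, 0) and np.allclose(vel.vy.values, 0)

    def test_translation_speed_within_20pct(self):
        # 0.5 px/frame: 0.2 µm/min * 0.5 min / 0.2 µm px^-1
        fs = synthetic.make_flow_scene("translation", 0.2, (96, 96), dt=0.5,
                                       seed=1)
        vel = flow.smooth_field(flow.optic_flow(fs.frames[0], fs.frames[1],
                                                fs.dt))
        med = np.median(vel.speed[8:-8, 8:-8])
        assert abs(med - 0.2) / 0.2 < 0.2

    def test_negating_dt_negates_field(self):
        fs = synthetic.make_flow_scene("shear", 0.1, (48, 48), dt=0.5, seed=2)
        v1 = flow.optic_flow(fs.frames[0], fs.frames[1], fs.dt)
        v2 = flow.optic_flow(fs.frames[0], fs.frames[1], -fs.dt)
        assert np.allclose(v1.vx.values, -v2.vx.values)
        assert np.allclose(v1.vy.values, -v2.vy.values)

    def test_textureless_pixels_flagged_zero(self):
        a = np.zeros((32, 32)); a[10:20, 10:20] = 1.0
        b = np.roll(a, 1, axis=1).astype(float)
        vel = flow.optic_flow(PixelGrid(a), PixelGrid(b), dt=1.0)
        assert vel.degenerate[0, 0]
        assert vel.vx.values[0, 0] == 0.0

    def test_estimated_divergence_matches_closed_form(self):
        # fine speckle + wide Gaussian aggregation window: the recovered
        # divergence of a pure source matches 2c within 20% RMS pointwise
        errs = []
        for seed in (0, 1, 2):
            fs = synthetic.make_flow_scene("source", 0.05, (96, 96), dt=0.5,
                                           seed=seed)
            vel = flow.optic_flow(fs.frames[0], fs.frames[1], fs.dt,
                                  gaussian_window=8.0)
            div = flow.divergence(flow.smooth_field(vel)).values
            e = div[12:-12, 12:-12] - 0.1
            errs.append(np.sqrt(np.mean(e ** 2)) / 0.1)
        assert np.mean(errs) < 0.2


class TestSmoothField:
    def test_constant_field_unchanged(self):
        v = affine_velocity_field("translation")
        out = flow.smooth_field(v)
        assert np.allclose(out.vx.values, v.vx.values)

    def test_spike_spreads_to_ninth(self):
        vx = np.zeros((9, 9)); vx[4, 4] = 0.9
        v = flow.VelocityField(PixelGrid(vx), PixelGrid(np.zeros((9, 9))), 1.0)
        out = flow.smooth_field(v)
        assert np.allclose(out.vx.values[3:6, 3:6], 0.1)
        assert out.vx.values[0, 0] == 0.0

    def test_linear_field_preserved_in_interior(self):
        v = affine_velocity_field("shear")
        out = flow.smooth_field(v)
        assert np.allclose(out.vx.values[1:-1, 1:-1], v.vx.values[1:-1, 1:-1],
                           atol=1e-12)


class TestDivergenceAndStrain:
    @pytest.mark.parametrize("kind,expected_div", [
        ("source", 0.2), ("rotation", 0.0), ("translation", 0.0)])
    def test_divergence_closed_form(self, kind, expected_div):
        div = flow.divergence(affine_velocity_field(kind))
        assert np.allclose(div.values, expected_div, atol=1e-9)

    def test_shear_strain_tensor(self):
        sf = flow.strain_tensor(affine_velocity_field("shear", c=0.1))
        assert np.allclose(sf.S[..., 0, 0], 0, atol=1e-9)
        assert np.allclose(sf.gammaS, 0.05, atol=1e-9)
        assert np.allclose(sf.Lam1, 0.05, atol=1e-9)
        assert np.allclose(sf.Lam2, -0.05, atol=1e-9)

    def test_isotropic_expansion(self):
        sf = flow.strain_tensor(affine_velocity_field("source", c=0.1))
        assert np.allclose(sf.S[..., 0, 0], 0.1, atol=1e-9)
        assert np.allclose(sf.S[..., 0, 1], 0.0, atol=1e-9)
        assert np.allclose(sf.Lam1, 0.1, atol=1e-9)
        assert np.allclose(sf.Lam2, 0.1, atol=1e-9)
        assert np.allclose(sf.S_dev, 0.0, atol=1e-9)

    def test_rigid_rotation_zero_strain(self):
        sf = flow.strain_tensor(affine_velocity_field("rotation", c=0.3))
        assert np.allclose(sf.S, 0.0, atol=1e-9)

    def test_exact_tensor_identities_on_noisy_field(self):
        rng = np.random.default_rng(0)
        v = flow.VelocityField(PixelGrid(rng.random((24, 24)), 0.2, 0.2),
                               PixelGrid(rng.random((24, 24)), 0.2, 0.2), 1.0)
        sf = flow.strain_tensor(v)
        assert np.allclose(sf.S, sf.S_area + sf.S_dev, atol=1e-9)
        assert np.allclose(sf.S_dev[..., 0, 0] + sf.S_dev[..., 1, 1], 0, atol=1e-9)
        assert np.allclose(sf.S[..., 0, 0] + sf.S[..., 1, 1], sf.div.values,
                           atol=1e-9)
        assert np.all(sf.Lam1 >= sf.Lam2 - 1e-12)
        assert np.allclose(sf.Lam1 + sf.Lam2, sf.div.values, atol=1e-9)
        assert np.allclose(sf.lam1_dev, -sf.lam2_dev, atol=1e-12)


class TestEventVelocities:
    def test_source_scene_shrinkage_events(self, source_flow_scene):
        fs = source_flow_scene
        vel = flow.smooth_field(flow.optic_flow(fs.frames[0], fs.frames[1],
                                                fs.dt, gaussian_window=8.0))
        div = flow.divergence(vel)
        interior = np.zeros(div.values.shape, dtype=bool)
        interior[12:-12, 12:-12] = True
        d = np.where(interior, div.values, 0.0)
        ev = flow.event_velocities(vel, div.with_values(d), threshold=0.12)
        assert ev.n_shrink_px > 0
        # pure source: only positive divergence above threshold
        assert ev.n_growth_px < 0.05 * ev.n_shrink_px
        vx_t, vy_t = fs.v_true
        truth = np.hypot(vx_t, vy_t)[d > 0.12].mean()
        assert abs(ev.v_shrinkage - truth) / truth < 0.2

    def test_infinite_threshold_empty_sets(self):
        v = affine_velocity_field("source")
        div = flow.divergence(v)
        ev = flow.event_velocities(v, div, threshold=np.inf)
        assert ev.n_growth_px == 0 and ev.n_shrink_px == 0
        assert np.isnan(ev.v_growth) and np.isnan(ev.v_shrinkage)

    def test_sign_flip_swaps_growth_and_shrinkage(self):
        v = affine_velocity_field("source", c=0.2)
        div = flow.divergence(v)
        ev_pos = flow.event_velocities(v, div, threshold=0.12)
        neg = flow.VelocityField(v.vx.with_values(-v.vx.values),
                                 v.vy.with_values(-v.vy.values), v.dt)
        ev_neg = flow.event_velocities(neg, flow.divergence(neg), threshold=0.12)
        assert ev_pos.n_shrink_px == ev_neg.n_growth_px
        assert ev_pos.n_growth_px == ev_neg.n_shrink_px


class TestPrincipalStrain:
    def test_pure_shear_unit_magnitude(self):
        S = np.zeros((1, 1, 2, 2))
        S[0, 0] = [[0, 0.5], [0.5, 0]]
        S_area, S_dev, l1, l2 = flow.area_deviatoric_split(S)
        sf = flow.StrainField(div=PixelGrid(np.ones((1, 1))), V=S, S=S,
                              gammaS=S[..., 0, 1], Lam1=l1, Lam2=l2,
                              S_area=S_area, S_dev=S_dev,
                              lam1_dev=l1, lam2_dev=l2)
        assert sf.principal_mag[0, 0] == pytest.approx(1.0)

    def test_zero_field_zero_series(self):
        v = affine_velocity_field("translation", c=0.0)
        sf = flow.strain_tensor(v)
        series, mean = flow.principal_strain_series(
            [sf], [np.ones(v.vx.shape, dtype=bool)])
        assert len(series) == 0 and np.isnan(mean)

    def test_magnitude_scales_linearly_with_shear(self):
        # two movies whose shear magnitudes differ by x1.14: the
        # time-averaged principal strain magnitude scales by the same ratio
        means = []
        for mag in (0.1, 0.114):
            fs = synthetic.make_flow_scene("shear", mag, (96, 96), dt=0.5,
                                           seed=3, n_frames=3)
            sfs, masks = [], []
            for t in range(2):
                vel = flow.smooth_field(flow.optic_flow(
                    fs.frames[t], fs.frames[t + 1], fs.dt, gaussian_window=8.0))
                sf = flow.strain_tensor(vel)
                sfs.append(sf)
                m = np.zeros(vel.vx.shape, dtype=bool)
                m[12:-12, 12:-12] = True
                masks.append(m)
            _, mean = flow.principal_strain_series(sfs, masks)
            means.append(mean)
        assert means[1] / means[0] == pytest.approx(1.14, rel=0.05)
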