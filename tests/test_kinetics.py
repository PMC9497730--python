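"""Uptake kinetics: baseline subtraction, ROI means, exponential fits,
saturation time, depth profiles and layer summaries."""

import numpy as np
import pytest

from cartidiff.containers import RoiSpec
from cartidiff.kinetics import (
    centered_cartilage_roi,
    depth_profile,
    fit_uptake_curve,
    layer_summary,
    relative_concentration,
    roi_mean,
    saturation_time,
    subtract_baseline,
)
from cartidiff.synthetic.planar import render_planar_series
from cartidiff.synthetic.slab import (
    PLUG_TIME_GRID_H,
    SlabDiffusionConfig,
    solve_slab_diffusion,
)


@pytest.fixture(scope="module")
def rendered(micro_calibration):
    field = solve_slab_diffusion(SlabDiffusionConfig(nx=120))
    return field, render_planar_series(field, micro_calibration, noise_sd=0.0)


class TestSubtractBaseline:
    def test_baseline_equals_images_gives_zero(self, rendered):
        _, series = rendered
        import dataclasses

        flat = dataclasses.replace(
            series, images=np.broadcast_to(series.baseline, series.images.shape)
        )
        sub = subtract_baseline(flat)
        assert np.all(sub.images == 0.0)

    def test_double_subtraction_guarded_by_flag(self, rendered):
        _, series = rendered
        sub = subtract_baseline(series)
        assert sub.baseline_subtracted
        with pytest.raises(ValueError, match="already"):
            subtract_baseline(sub)

    def test_recovers_known_increment(self, rendered, micro_calibration):
        field, series = rendered
        sub = subtract_baseline(series)
        # bath band carries the forward-mapped bath concentration exactly
        r = series.geometry.bath_rows[0]
        expected = micro_calibration.a + micro_calibration.b * field.c_bath[-1]
        assert sub.images[-1][r, 0] == pytest.approx(expected, abs=1e-9)


class TestRoiMean:
    def test_constant_image(self):
        img = np.full((20, 20), 7.0)
        mean, sd, n = roi_mean(img, RoiSpec("rect", (9.5, 9.5), width=10, height=10))
        assert (mean, sd) == (7.0, 0.0)

    def test_small_block_arithmetic(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        mean, _, n = roi_mean(img, RoiSpec("rect", (0.5, 0.5), width=1, height=1))
        assert mean == pytest.approx(2.5)
        assert n == 4

    def test_circle_count_matches_bruteforce(self):
        img = np.ones((31, 31))
        _, _, n = roi_mean(img, RoiSpec("circle", (15.0, 15.0), radius=5.0))
        brute = sum(
            1
            for dr in range(-6, 7)
            for dc in range(-6, 7)
            if dr * dr + dc * dc <= 25
        )
        assert n == brute == 81

    def test_out_of_bounds_rejected(self):
        img = np.ones((10, 10))
        with pytest.raises(ValueError, match="bounds"):
            roi_mean(img, RoiSpec("rect", (5.0, 5.0), width=30, height=2))

    def test_default_roi_is_100px_wide(self, rendered):
        _, series = rendered
        roi = centered_cartilage_roi(series)
        _, _, n = roi_mean(series.images[0], roi)
        assert n == 100 * series.geometry.n_cartilage_rows


class TestUptakeFit:
    def test_noiseless_recovery_on_bench_grid(self):
        t = np.asarray(PLUG_TIME_GRID_H)
        y = 10.0 * (1.0 - np.exp(-t / 2.0))
        fit = fit_uptake_curve(t, y)
        assert fit.a == pytest.approx(10.0, abs=1e-6)
        assert fit.tau == pytest.approx(2.0, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_value_at_tau_is_63_percent_of_plateau(self):
        t = np.asarray(PLUG_TIME_GRID_H)
        fit = fit_uptake_curve(t, 5.0 * (1.0 - np.exp(-t / 0.7)))
        assert fit.predict(fit.tau) == pytest.approx(
            (1.0 - np.exp(-1.0)) * fit.a, rel=1e-9
        )

    def test_noisy_tau_recovery_monte_carlo(self):
        t = np.asarray(PLUG_TIME_GRID_H)
        a, tau = 10.0, 0.4
        truth = a * (1.0 - np.exp(-t / tau))
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(200):
            fit = fit_uptake_curve(t, truth + rng.normal(0, 0.05 * a, t.size))
            errs.append(abs(fit.tau - tau) / tau)
        assert np.median(errs) < 0.10

    def test_t0_excluded_by_default(self):
        t = np.concatenate([[0.0], np.asarray(PLUG_TIME_GRID_H)])
        y = 4.0 * (1.0 - np.exp(-t / 1.5))
        fit = fit_uptake_curve(t, y)
        assert fit.residuals.size == len(PLUG_TIME_GRID_H)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_uptake_curve([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="all equal"):
            fit_uptake_curve([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestSaturationTime:
    @pytest.mark.parametrize("tau,expected", [(1.0, 5.0), (0.38, 1.9), (0.52, 2.6)])
    def test_nominal_convention_is_5_tau(self, tau, expected):
        t = np.asarray(PLUG_TIME_GRID_H)
        fit = fit_uptake_curve(t, 3.0 * (1.0 - np.exp(-t / tau)))
        assert saturation_time(fit) == pytest.approx(expected, rel=1e-6)

    def test_exact_option_is_ln20_tau(self):
        t = np.asarray(PLUG_TIME_GRID_H)
        fit = fit_uptake_curve(t, 3.0 * (1.0 - np.exp(-t / 1.0)))
        assert saturation_time(fit, exact=True) == pytest.approx(np.log(20.0), rel=1e-6)
        assert saturation_time(fit, exact=True) == pytest.approx(2.996, abs=1e-3)

    def test_linear_in_tau(self):
        t = np.asarray(PLUG_TIME_GRID_H)
        f1 = fit_uptake_curve(t, 3.0 * (1.0 - np.exp(-t / 0.5)))
        f2 = fit_uptake_curve(t, 3.0 * (1.0 - np.exp(-t / 1.0)))
        assert saturation_time(f2) == pytest.approx(2 * saturation_time(f1), rel=1e-6)


class TestDepthProfile:
    def test_constant_image_flat_profile(self):
        prof = depth_profile(np.full((40, 30), 3.0), (10, 30))
        assert np.allclose(prof.attenuation, 3.0)
        assert prof.depth[0] == 0.0 and prof.depth[-1] == 1.0

    def test_linear_ramp_linear_profile(self):
        img = np.tile(np.arange(40.0)[:, None], (1, 8))
        prof = depth_profile(img, (0, 40))
        assert prof.attenuation[0] == 0.0
        assert prof.attenuation[-1] == 39.0
        assert np.allclose(np.diff(prof.attenuation), 1.0)

    def test_late_time_profile_flat_at_equilibrium(self, micro_calibration):
        field = solve_slab_diffusion(
            SlabDiffusionConfig(finite_bath=False, times=(100.0,), nx=120)
        )
        series = render_planar_series(field, micro_calibration, noise_sd=0.0)
        sub = subtract_baseline(series)
        prof = depth_profile(sub.images[0], series.geometry.cartilage_rows)
        expected = micro_calibration.a + micro_calibration.b * (
            field.config.kappa * field.config.c_bath0
        )
        assert np.allclose(prof.attenuation, expected, rtol=1e-3)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            depth_profile(np.ones((10, 10)), (4, 4))


class TestLayerSummary:
    def test_flat_profile(self):
        prof = depth_profile(np.full((30, 5), 2.0), (0, 30))
        assert layer_summary(prof) == (2.0, 2.0, 2.0)

    def test_monotone_profile_orders_layers(self):
        img = np.tile(np.arange(30.0)[:, None], (1, 5))
        sup, mid, deep = layer_summary(depth_profile(img, (0, 30)))
        assert sup < mid < deep

    def test_early_diffusion_loads_superficial_layer(self, micro_calibration):
        field = solve_slab_diffusion(
            SlabDiffusionConfig(finite_bath=False, times=(0.02,), nx=120)
        )
        series = render_planar_series(field, micro_calibration, noise_sd=0.0)
        sub = subtract_baseline(series)
        sup, _, deep = layer_summary(
            depth_profile(sub.images[0], series.geometry.cartilage_rows)
        )
        assert sup > deep

    def test_tertile_means_average_to_profile_mean(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (90, 7))
        prof = depth_profile(img, (0, 90))
        layers = layer_summary(prof)
        assert np.mean(layers) == pytest.approx(prof.attenuation.mean(), rel=1e-9)


class TestRelativeConcentration:
    @pytest.mark.parametrize(
        "cc,cb,expected", [(10.0, 10.0, 1.0), (0.0, 5.0, 0.0), (21.2, 3.3432, 6.3412)]
    )
    def test_ratio(self, cc, cb, expected):
        assert relative_concentration(cc, cb) == pytest.approx(expected, abs=2e-4)

    def test_nonpositive_bath_rejected(self):
        with pytest.raises(ValueError):
            relative_concentration(1.0, 0.0)
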