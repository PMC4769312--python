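"""One-tissue water model: forward curves, fitting, input correction, ridge maps."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from neuropet._kinetics import expconv, fine_grid, frame_average_fine, sample_curve
from neuropet.core_io import BloodCurve, DynamicImage, VolumeGeometry
from neuropet.phantom import degrade_input
from neuropet.water_kinetics import (
    DelayDispersion,
    OneTissueParams,
    TissueCurve,
    correct_delay_dispersion,
    fit_one_tissue,
    flow_map,
    frame_average,
    normalize_map,
    one_tissue_tac,
    ridge_parametric_fit,
)


class TestForwardModel:
    def test_no_delivery_gives_zero(self, arterial_input):
        p = OneTissueParams(0.0, 0.3, 0.0)
        out = one_tissue_tac(p, arterial_input, np.linspace(0, 5, 20))
        np.testing.assert_allclose(out, 0.0)

    def test_constant_input_no_clearance_accumulates_linearly(self):
        cb = BloodCurve(np.arange(6.0), np.full(6, 10.0))
        p = OneTissueParams(0.5, 0.0, 0.0)
        assert one_tissue_tac(p, cb, [2.0])[0] == pytest.approx(10.0, rel=1e-9)

    def test_constant_input_saturating_closed_form(self):
        cb = BloodCurve(np.arange(6.0), np.full(6, 10.0))
        p = OneTissueParams(0.5, 0.25, 0.0)
        expected = (0.5 * 10 / 0.25) * (1 - np.exp(-0.25 * 4.0))
        assert one_tissue_tac(p, cb, [4.0])[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(12.642, abs=5e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_convolution_matches_stiff_ode_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 5, 26)
        v = np.abs(rng.normal(50, 20, 26))
        v[0] = 0.0
        grid = fine_grid(5.0)
        cb = sample_curve(t, v, grid)
        K1, k2 = rng.uniform(0.1, 0.8), rng.uniform(0.1, 1.5)
        sol = solve_ivp(lambda tt, y: K1 * np.interp(tt, grid, cb) - k2 * y,
                        (0, 5), [0.0], t_eval=grid, rtol=1e-10, atol=1e-12,
                        max_step=0.01)
        mine = K1 * expconv(cb, k2)
        rel = np.max(np.abs(mine - sol.y[0])) / np.max(np.abs(sol.y[0]))
        assert rel <= 1e-6


class TestFrameAverage:
    def test_constant_curve(self, water_grid, water_schedule):
        tac = frame_average(np.full_like(water_grid, 7.0), water_grid, water_schedule)
        np.testing.assert_allclose(tac.value, 7.0)

    def test_linear_curve_averages_to_midpoint(self, water_grid, water_schedule):
        a = 3.0
        tac = frame_average(a * water_grid, water_grid, water_schedule)
        np.testing.assert_allclose(tac.value, a * water_schedule.mid_times_min, rtol=1e-9)

    def test_matches_quadrature_oracle_on_random_curve(self, water_grid, water_schedule):
        rng = np.random.default_rng(0)
        smooth = np.cumsum(rng.normal(size=water_grid.size)) * 0.01
        tac = frame_average(smooth, water_grid, water_schedule)
        for f in range(0, len(water_schedule), 5):
            lo = water_schedule.start_s[f] / 60.0
            hi = water_schedule.end_s[f] / 60.0
            inside = water_grid[(water_grid > lo) & (water_grid < hi)]
            xs = np.concatenate([[lo], inside, [hi]])
            ys = np.interp(xs, water_grid, smooth)
            oracle = np.trapezoid(ys, xs) / (hi - lo)
            assert tac.value[f] == pytest.approx(oracle, abs=1e-6)


class TestFitOneTissue:
    def test_noiseless_recovery_within_half_percent(self, arterial_input, water_grid,
                                                    water_schedule):
        true = OneTissueParams(0.4, 0.5, 0.03)
        cont = one_tissue_tac(true, arterial_input, water_grid)
        tac = frame_average(cont, water_grid, water_schedule)
        est, wrss = fit_one_tissue(tac, arterial_input)
        assert est.K1 == pytest.approx(true.K1, rel=5e-3)
        assert est.k2 == pytest.approx(true.k2, rel=5e-3)
        assert est.Vb == pytest.approx(true.Vb, rel=5e-3)

    def test_all_zero_tac_returns_zero_flow(self, arterial_input, water_schedule):
        tac = TissueCurve(water_schedule.mid_times_min,
                          np.zeros(len(water_schedule)),
                          np.ones(len(water_schedule)), water_schedule)
        est, wrss = fit_one_tissue(tac, arterial_input)
        assert est.K1 == 0.0 and wrss == 0.0

    def test_vascular_only_limit(self, arterial_input, water_grid, water_schedule):
        true_vb = 0.08
        cont = one_tissue_tac(OneTissueParams(0.0, 0.0, true_vb), arterial_input, water_grid)
        tac = frame_average(cont, water_grid, water_schedule)
        est, _ = fit_one_tissue(tac, arterial_input)
        assert est.Vb == pytest.approx(true_vb, abs=1e-3)
        assert est.K1 <= 1e-6

    def test_scale_equivariance(self, arterial_input, water_grid, water_schedule):
        true = OneTissueParams(0.3, 0.4, 0.05)
        cont = one_tissue_tac(true, arterial_input, water_grid)
        tac = frame_average(cont, water_grid, water_schedule)
        c = 3.7
        scaled_input = BloodCurve(arterial_input.time_min, arterial_input.value * c)
        scaled_tac = TissueCurve(tac.time_min, tac.value * c, tac.weight, tac.schedule)
        est, _ = fit_one_tissue(scaled_tac, scaled_input)
        assert est.K1 == pytest.approx(true.K1, rel=1e-3)
        assert est.k2 == pytest.approx(true.k2, rel=1e-3)
        assert est.Vb == pytest.approx(true.Vb, abs=1e-3)

    def test_nonfinite_values_rejected(self, arterial_input, water_schedule):
        vals = np.ones(len(water_schedule))
        vals[3] = np.nan
        tac = TissueCurve(water_schedule.mid_times_min, vals,
                          np.ones(len(water_schedule)), water_schedule)
        with pytest.raises(ValueError):
            fit_one_tissue(tac, arterial_input)


class TestDelayDispersion:
    def _whole_brain(self, arterial_input, water_grid, water_schedule):
        true = OneTissueParams(0.35, 0.4, 0.04)
        cont = one_tissue_tac(true, arterial_input, water_grid)
        return frame_average(cont, water_grid, water_schedule)

    def test_zero_degradation_recovers_zero(self, arterial_input, water_grid,
                                            water_schedule):
        wb = self._whole_brain(arterial_input, water_grid, water_schedule)
        measured = degrade_input(arterial_input, DelayDispersion(0.0, 0.0))
        _, dd, _ = correct_delay_dispersion(
            measured, wb, delta_range_s=(-3, 3), tau_max_s=6.0)
        assert dd.delta_t_s == 0.0
        assert dd.tau_s == 0.0

    def test_shift_equivariance(self, arterial_input, water_grid, water_schedule):
        wb = self._whole_brain(arterial_input, water_grid, water_schedule)
        recovered = []
        for shift in (2.0, 4.0):
            measured = degrade_input(arterial_input, DelayDispersion(shift, 3.0))
            _, dd, _ = correct_delay_dispersion(
                measured, wb, delta_range_s=(0, 6), tau_max_s=5.0)
            recovered.append(dd.delta_t_s)
        assert recovered[1] - recovered[0] == pytest.approx(2.0, abs=0.25)

    def test_flat_whole_brain_rejected(self, arterial_input, water_schedule):
        flat = TissueCurve(water_schedule.mid_times_min,
                           np.full(len(water_schedule), 5.0),
                           np.ones(len(water_schedule)), water_schedule)
        with pytest.raises(ValueError):
            correct_delay_dispersion(arterial_input, flat)


class TestRidgeParametricFit:
    def _image(self, arterial_input, water_grid, water_schedule, params, shape):
        cont = one_tissue_tac(params, arterial_input, water_grid)
        frames = frame_average(cont, water_grid, water_schedule).value
        data = np.tile(frames, shape + (1,))
        geom = VolumeGeometry(shape, (2.0, 2.0))
        return DynamicImage(data, geom, water_schedule), frames

    def test_unpenalized_matches_nls_within_one_percent(self, arterial_input,
                                                        water_grid, water_schedule):
        true = OneTissueParams(0.2805, 0.31, 0.04)
        img, frames = self._image(arterial_input, water_grid, water_schedule,
                                  true, (6, 6))
        maps = ridge_parametric_fit(img, arterial_input, np.ones((6, 6), bool),
                                    ridge=False)
        tac = TissueCurve(water_schedule.mid_times_min, frames,
                          np.ones(len(water_schedule)), water_schedule)
        nls, _ = fit_one_tissue(tac, arterial_input)
        assert maps["K1"].data[0, 0] == pytest.approx(nls.K1, rel=0.01)

    def test_ridge_reduces_rmse_under_noise(self, arterial_input, water_grid,
                                            water_schedule):
        true = OneTissueParams(0.2805, 0.31, 0.04)
        img, frames = self._image(arterial_input, water_grid, water_schedule,
                                  true, (25, 20))
        rng = np.random.default_rng(1)
        scale = np.sqrt(water_schedule.duration_s.max() / water_schedule.duration_s)
        noisy = img.data + 0.05 * img.data * scale * rng.standard_normal(img.data.shape)
        noisy_img = DynamicImage(noisy, img.geometry, water_schedule)
        mask = np.ones((25, 20), bool)
        plain = ridge_parametric_fit(noisy_img, arterial_input, mask, ridge=False)
        smooth = ridge_parametric_fit(noisy_img, arterial_input, mask, ridge=True)
        for name, tv in (("K1", true.K1), ("k2", true.k2), ("Vb", true.Vb)):
            rmse_plain = np.sqrt(np.mean((plain[name].data - tv) ** 2))
            rmse_ridge = np.sqrt(np.mean((smooth[name].data - tv) ** 2))
            assert rmse_ridge < rmse_plain

    def test_all_zero_dynamic_gives_zero_maps(self, arterial_input, water_schedule):
        geom = VolumeGeometry((4, 4), (2.0, 2.0))
        img = DynamicImage(np.zeros((4, 4, len(water_schedule))), geom, water_schedule)
        maps = ridge_parametric_fit(img, arterial_input, np.ones((4, 4), bool))
        np.testing.assert_allclose(maps["K1"].data, 0.0, atol=1e-9)

    def test_empty_mask_rejected(self, arterial_input, water_schedule):
        geom = VolumeGeometry((4, 4), (2.0, 2.0))
        img = DynamicImage(np.zeros((4, 4, len(water_schedule))), geom, water_schedule)
        with pytest.raises(ValueError):
            ridge_parametric_fit(img, arterial_input, np.zeros((4, 4), bool))


class TestFlowAndNormalization:
    def test_flow_conversion_examples(self):
        geom = VolumeGeometry((2, 2), (1.0, 1.0))
        k1 = np.full((2, 2), 0.2805)
        from neuropet.core_io import ParametricMap
        cbf = flow_map(ParametricMap("K1", k1, "1/min", geom), 0.85)
        np.testing.assert_allclose(cbf.data, 33.0, rtol=1e-12)
        cbf_e1 = flow_map(ParametricMap("K1", np.full((2, 2), 0.2), "1/min", geom), 1.0)
        np.testing.assert_allclose(cbf_e1.data, 20.0)
        zeros = flow_map(ParametricMap("K1", np.zeros((2, 2)), "1/min", geom))
        np.testing.assert_allclose(zeros.data, 0.0)

    def test_invalid_extraction_fraction(self):
        from neuropet.core_io import ParametricMap
        geom = VolumeGeometry((2, 2), (1.0, 1.0))
        pm = ParametricMap("K1", np.ones((2, 2)), "1/min", geom)
        with pytest.raises(ValueError):
            flow_map(pm, 0.0)

    def test_normalization(self):
        from neuropet.core_io import ParametricMap
        geom = VolumeGeometry((2, 2), (1.0, 1.0))
        pm = ParametricMap("CBF", np.full((2, 2), 40.0), "mL/100g/min", geom)
        out = normalize_map(pm, 38.4)
        np.testing.assert_allclose(out.data, 40.0 / 38.4)
        assert out.data[0, 0] == pytest.approx(1.0417, abs=1e-4)
        same = normalize_map(ParametricMap("x", np.full((2, 2), 3.0), "u", geom), 3.0)
        np.testing.assert_allclose(same.data, 1.0)
        with pytest.raises(ValueError):
            normalize_map(pm, 0.0)
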