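"""G-V construction and Boltzmann fitting: exactness, symmetry, recovery."""

import numpy as np
import pytest

from bkfit import (
    BoltzmannFit,
    GatingModel,
    GVCurve,
    boltzmann_popen,
    fit_boltzmann,
    make_gating_sweeps,
    steady_state_conductance,
    v_half_shift,
)

from conftest import MSLO1_VHALF, peak_current_pa


def exact_gv(v, v_half, kappa, g_max=1.0, noise=None):
    g = g_max * boltzmann_popen(v, v_half, kappa)
    if noise is not None:
        g = g + noise
    return GVCurve(v=v, g=g, g_norm=g / np.max(g))


class TestSteadyStateConductance:
    def test_noiseless_equals_gmax_times_popen(self, protocol, fast_gating_model):
        ss = make_gating_sweeps(fast_gating_model, protocol)
        with pytest.warns(UserWarning, match="zero driving force"):
            gv = steady_state_conductance(ss, e_rev=0.0)
        m = fast_gating_model
        expected = m.g_max * boltzmann_popen(gv.v, m.v_half, m.kappa)
        np.testing.assert_allclose(gv.g, expected, rtol=1e-9)
        # the 0 mV step coincides with E_rev and must have been dropped
        assert 0.0 not in gv.v
        assert len(gv.v) == len(protocol.step_voltages) - 1

    def test_all_points_dropped_fails(self, fast_gating_model):
        from bkfit import StepProtocol
        proto = StepProtocol(step_voltages=[0.0])
        ss = make_gating_sweeps(fast_gating_model, proto)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="dropped"):
                steady_state_conductance(ss, e_rev=0.0)

    def test_bad_tail_fraction_rejected(self, protocol, fast_gating_model):
        ss = make_gating_sweeps(fast_gating_model, protocol)
        for bad in (0.0, 0.6, -0.1):
            with pytest.raises(ValueError):
                steady_state_conductance(ss, tail_fraction=bad)

    def test_gnorm_near_one_at_saturation_under_noise(self, protocol):
        # +140 mV is deep in the saturated limb: normalized conductance
        # there stays within 2% of 1 under 2%-of-peak current noise
        base = GatingModel(v_half=MSLO1_VHALF, tau_params=2.0)
        sd = 0.02 * peak_current_pa(base, protocol)
        errs = []
        for seed in range(100):
            m = GatingModel(v_half=MSLO1_VHALF, tau_params=2.0,
                            noise_sd=sd, seed=seed)
            ss = make_gating_sweeps(m, protocol)
            with pytest.warns(UserWarning, match="zero driving force"):
                gv = steady_state_conductance(ss)
            errs.append(abs(gv.g_norm[list(gv.v).index(140.0)] - 1.0))
        assert np.median(errs) <= 0.02


class TestFitBoltzmann:
    def test_roundtrip_recovers_vhalf_to_1e6(self, protocol, fast_gating_model):
        ss = make_gating_sweeps(fast_gating_model, protocol)
        with pytest.warns(UserWarning, match="zero driving force"):
            gv = steady_state_conductance(ss)
        fit = fit_boltzmann(gv)
        assert fit.converged
        assert abs(fit.v_half - MSLO1_VHALF) / MSLO1_VHALF <= 1e-6
        assert fit.kappa == pytest.approx(-16.0, rel=1e-6)
        assert fit.kappa < 0  # activating convention
        assert fit.slope_k == pytest.approx(16.0, rel=1e-6)

    def test_exact_points_any_activating_kappa(self):
        v = np.arange(-140.0, 141.0, 20.0)
        for kappa in (-8.0, -16.0, -25.0):
            fit = fit_boltzmann(exact_gv(v, MSLO1_VHALF, kappa))
            assert fit.v_half == pytest.approx(MSLO1_VHALF, abs=1e-6)
            assert fit.kappa == pytest.approx(kappa, rel=1e-6)

    def test_refit_of_fitted_curve_is_idempotent(self):
        v = np.arange(-140.0, 141.0, 20.0)
        rng = np.random.default_rng(42)
        gv = exact_gv(v, 10.0, -14.0, g_max=8.0, noise=rng.normal(0, 0.05, v.size))
        fit1 = fit_boltzmann(gv)
        g2 = fit1.predict(v)
        fit2 = fit_boltzmann(GVCurve(v=v, g=g2, g_norm=g2 / np.max(g2)))
        assert fit2.v_half == pytest.approx(fit1.v_half, rel=1e-9)
        assert fit2.kappa == pytest.approx(fit1.kappa, rel=1e-9)
        assert fit2.g_max == pytest.approx(fit1.g_max, rel=1e-9)

    def test_mirrored_curve_flips_kappa_sign_only(self):
        v = np.arange(-120.0, 121.0, 20.0)
        vh, kappa = 12.5, -15.0
        fwd = fit_boltzmann(exact_gv(v, vh, kappa))
        g = boltzmann_popen(v, vh, kappa)
        v_mirror = (2 * vh - v)[::-1]
        g_mirror = g[::-1]
        rev = fit_boltzmann(GVCurve(v=v_mirror, g=g_mirror,
                                    g_norm=g_mirror / np.max(g_mirror)))
        assert rev.v_half == pytest.approx(fwd.v_half, abs=1e-6)
        assert rev.kappa == pytest.approx(-fwd.kappa, rel=1e-6)

    def test_scale_invariance(self):
        # binary-exact scale factors keep the internally normalized data
        # bitwise identical, so the shape parameters cannot move at all;
        # inexact factors perturb the inputs at 1 ulp and are not exact
        v = np.arange(-100.0, 101.0, 20.0)
        rng = np.random.default_rng(7)
        noise = rng.normal(0, 0.02, v.size)
        base = fit_boltzmann(exact_gv(v, 5.0, -12.0, noise=noise))
        for c in (0.125, 4.0, 256.0):
            g = (boltzmann_popen(v, 5.0, -12.0) + noise) * c
            scaled = fit_boltzmann(GVCurve(v=v, g=g, g_norm=g / np.max(g)))
            assert scaled.v_half == pytest.approx(base.v_half, rel=1e-9)
            assert scaled.kappa == pytest.approx(base.kappa, rel=1e-9)
            assert scaled.g_max == pytest.approx(base.g_max * c, rel=1e-9)

    def test_grid_search_oracle_agrees(self):
        # brute-force SSE minimum over (v_half, kappa) with the optimal
        # g_max solved in closed form per grid node
        v = np.arange(-60.0, 61.0, 20.0)
        rng = np.random.default_rng(11)
        g = boltzmann_popen(v, 5.0, -12.0) + rng.normal(0, 0.02, v.size)
        gv = GVCurve(v=v, g=g, g_norm=g / np.max(g))
        fit = fit_boltzmann(gv)

        vh_grid = np.arange(0.0, 10.0001, 0.01)
        k_grid = np.arange(-16.0, -7.9999, 0.02)
        p = 1.0 / (1.0 + np.exp(
            (v[None, None, :] - vh_grid[:, None, None]) / k_grid[None, :, None]))
        gmax_opt = (p @ g) / np.sum(p * p, axis=-1)
        sse = np.sum((gmax_opt[..., None] * p - g[None, None, :]) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)

        assert abs(fit.v_half - vh_grid[i]) <= 0.01
        assert abs(fit.kappa - k_grid[j]) <= 0.02
        assert fit.rss <= sse[i, j] + 1e-12

    def test_fix_gmax_pins_to_max(self):
        v = np.arange(-100.0, 101.0, 20.0)
        gv = exact_gv(v, 5.0, -12.0, g_max=7.0)
        fit = fit_boltzmann(gv, fix_gmax=True)
        assert fit.g_max == float(np.max(gv.g))
        assert fit.v_half == pytest.approx(5.0, abs=0.5)

    def test_monte_carlo_vhalf_recovery(self, protocol):
        # 2%-of-peak current noise, 100 seeds: median error <= 1 mV,
        # 95th percentile <= 5 mV
        base = GatingModel(v_half=MSLO1_VHALF, tau_params=2.0)
        sd = 0.02 * peak_current_pa(base, protocol)
        errs = []
        for seed in range(100):
            m = GatingModel(v_half=MSLO1_VHALF, tau_params=2.0,
                            noise_sd=sd, seed=seed)
            ss = make_gating_sweeps(m, protocol)
            with pytest.warns(UserWarning, match="zero driving force"):
                gv = steady_state_conductance(ss)
            errs.append(abs(fit_boltzmann(gv).v_half - MSLO1_VHALF))
        errs = np.array(errs)
        assert np.median(errs) <= 1.0
        assert np.quantile(errs, 0.95) <= 5.0

    def test_too_few_voltages_rejected(self):
        v = np.array([-20.0, 0.0, 20.0])
        g = boltzmann_popen(v, 5.0, -12.0)
        with pytest.raises(ValueError, match="4 distinct"):
            fit_boltzmann(GVCurve(v=v, g=g, g_norm=g / g.max()))

    def test_flat_data_rejected(self):
        v = np.arange(-60.0, 61.0, 20.0)
        g = np.full_like(v, 3.0)
        with pytest.raises(ValueError, match="flat"):
            fit_boltzmann(GVCurve(v=v, g=g, g_norm=g / g.max()))

    def test_one_sided_data_rejected(self):
        # all points in the saturated limb: no half-max crossing to fit
        v = np.arange(100.0, 241.0, 20.0)
        g = boltzmann_popen(v, 5.0, -12.0)
        with pytest.raises(ValueError, match="half-max"):
            fit_boltzmann(GVCurve(v=v, g=g, g_norm=g / g.max()))


def _fit(v_half, se=0.5):
    return BoltzmannFit(v_half=v_half, kappa=-15.0, g_max=1.0, se_v_half=se,
                        se_kappa=0.5, rss=0.0, n_iter=1, converged=True)


class TestVHalfShift:
    def test_identity(self):
        s = v_half_shift(_fit(MSLO1_VHALF), _fit(MSLO1_VHALF))
        assert s.delta_mv == 0.0 and s.fractional == 0.0

    def test_activating_shift_is_negative(self):
        # beta4(N123A)-like construct against the alpha-alone reference
        s = v_half_shift(_fit(-2.53), _fit(30.39))
        assert s.delta_mv == pytest.approx(-32.92)
        assert s.delta_mv < 0
        assert s.fractional == pytest.approx(-32.92 / 30.39)

    def test_rightward_shift(self):
        s = v_half_shift(_fit(38.89), _fit(30.39))
        assert s.delta_mv == pytest.approx(8.50)

    def test_zero_reference_has_no_fractional_shift(self):
        s = v_half_shift(_fit(10.0), _fit(0.0))
        assert s.delta_mv == 10.0 and s.fractional is None

    def test_requires_converged_fits(self):
        bad = _fit(10.0)
        bad.converged = False
        with pytest.raises(ValueError, match="converged"):
            v_half_shift(bad, _fit(0.0))
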