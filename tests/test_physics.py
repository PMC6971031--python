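"""Closed-form model tests: MSD laws, DLS/DWS, decay line, TPSF, IRF."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inirs import physics as ph
from inirs._constants import C_CM_S, PS


@pytest.fixture
def optics():
    return ph.OpticalProperties(mu_a=0.045, mu_s_prime=10.0, n_r=1.33, lambda0=855.0)


class TestMSD:
    @pytest.mark.parametrize(
        "model,tau,expected",
        [
            (ph.MSDModel(kind="brownian", D_B=1.0), 1.0, 6.0),
            (ph.MSDModel(kind="brownian", D_B=1.0), 0.0, 0.0),
            (ph.MSDModel(kind="random_flow", v=2.0), 3.0, 36.0),
            (ph.MSDModel(kind="hybrid", D_B=1.0, v=2.0), 1.0, 10.0),
        ],
    )
    def test_direct_substitution(self, model, tau, expected):
        assert ph.msd(model, tau) == pytest.approx(expected)

    def test_hydrodynamic_short_time_ballistic_limit(self):
        # second-order expansion: msd ~ 3 D_B tau^2/tau_C for tau << tau_C
        m = ph.MSDModel(kind="hydrodynamic", D_B=2.0, tau_C=1e-3)
        tau = m.tau_C / 100
        assert ph.msd(m, tau) == pytest.approx(3 * m.D_B * tau**2 / m.tau_C, rel=0.01)

    def test_hydrodynamic_converges_to_brownian_for_small_tau_C(self):
        tau = 1e-3
        m = ph.MSDModel(kind="hydrodynamic", D_B=2.0, tau_C=1e-12)
        assert ph.msd(m, tau) == pytest.approx(6 * 2.0 * tau, rel=1e-6)

    def test_hybrid_limits(self):
        tau = np.logspace(-6, -2, 20)
        brown = ph.MSDModel(kind="brownian", D_B=3.0)
        hyb_b = ph.MSDModel(kind="hybrid", D_B=3.0, v=0.0)
        np.testing.assert_allclose(ph.msd(hyb_b, tau), ph.msd(brown, tau), rtol=1e-9)
        flow = ph.MSDModel(kind="random_flow", v=3.0)
        hyb_f = ph.MSDModel(kind="hybrid", D_B=0.0, v=3.0)
        np.testing.assert_allclose(ph.msd(hyb_f, tau), ph.msd(flow, tau), rtol=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(
        kind=st.sampled_from(["brownian", "random_flow", "hybrid"]),
        D_B=st.floats(0.0, 1e-6),
        v=st.floats(0.0, 1.0),
    )
    def test_nonnegative_nondecreasing_zero_at_origin(self, kind, D_B, v):
        m = ph.MSDModel(kind=kind, D_B=D_B, v=v)
        tau = np.linspace(0.0, 1e-2, 50)
        out = np.asarray(ph.msd(m, tau))
        assert out[0] == 0.0
        assert np.all(out >= 0)
        assert np.all(np.diff(out) >= -1e-30)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            ph.msd(ph.MSDModel(kind="brownian", D_B=1.0), -1.0)

    def test_hydrodynamic_requires_tau_C(self):
        with pytest.raises(ValueError):
            ph.MSDModel(kind="hydrodynamic", D_B=1.0)


class TestDLSDWS:
    def test_all_static_limit(self):
        m = ph.MSDModel(kind="brownian", D_B=1e-8)
        tau = np.logspace(-6, -1, 10)
        np.testing.assert_allclose(ph.g1_dls(1.0, 1e5, m, tau), 1.0)

    def test_fully_dynamic_brownian_is_exponential(self):
        m = ph.MSDModel(kind="brownian", D_B=1e-8)
        q = 1e5
        tau = np.logspace(-6, -2, 10)
        np.testing.assert_allclose(
            ph.g1_dls(0.0, q, m, tau), np.exp(-(q**2) * m.D_B * tau), rtol=1e-12
        )

    def test_half_static_hand_value(self):
        # q^2 D_B tau = ln 2: 0.5 + 0.5 * 0.5 = 0.75
        m = ph.MSDModel(kind="brownian", D_B=1.0)
        q = 1.0
        tau = np.log(2.0)
        assert ph.g1_dls(0.5, q, m, tau) == pytest.approx(0.75, rel=1e-12)

    def test_dws_unity_at_zero_lag(self, optics):
        m = ph.MSDModel(kind="brownian", D_B=1e-8)
        assert ph.g1_dws(500.0, 0.0, optics, m) == pytest.approx(1.0)

    def test_dws_log_derivative_matches_decay_rate_line(self, optics):
        # -d ln g1 / d tau_d equals xi(tau_s) with tau_s0 = 0 for Brownian motion
        bfi = 1.18e-8
        m = ph.MSDModel(kind="brownian", D_B=bfi)
        tau_s = 200.0
        eps = 1e-7
        num = -(
            np.log(ph.g1_dws(tau_s, eps, optics, m)) - np.log(ph.g1_dws(tau_s, 0.0, optics, m))
        ) / eps
        assert num == pytest.approx(ph.decay_rate_line(tau_s, bfi, optics, 0.0), rel=1e-6)

    def test_dws_direct_evaluation(self, optics):
        # independent evaluation of the exponent at 200 ps
        bfi = 1.18e-8
        m = ph.MSDModel(kind="brownian", D_B=bfi)
        tau_s, tau_d = 200.0, 1e-4
        k = 2 * np.pi * 1.33 / (855e-7)
        expo = 2 * k**2 * bfi * 10.0 * C_CM_S * (tau_s * PS) / 1.33 * tau_d
        assert ph.g1_dws(tau_s, tau_d, optics, m) == pytest.approx(np.exp(-expo), rel=1e-10)

    def test_monotone_decreasing_in_tof_and_lag(self, optics):
        m = ph.MSDModel(kind="brownian", D_B=1e-8)
        tofs = np.linspace(50, 1000, 20)
        g_tof = ph.g1_dws(tofs, 1e-4, optics, m)
        assert np.all(np.diff(g_tof) < 0)
        lags = np.linspace(0, 1e-3, 20)
        g_lag = ph.g1_dws(500.0, lags, optics, m)
        assert np.all(np.diff(g_lag) < 0)
        assert np.all((g_lag > 0) & (g_lag <= 1))


class TestDecayLine:
    @settings(derandomize=True, max_examples=50)
    @given(
        bfi=st.floats(1e-10, 1e-6),
        mu_sp=st.floats(1.0, 30.0),
        n_r=st.floats(1.3, 1.5),
        lam=st.floats(600.0, 1000.0),
    )
    def test_round_trip_slope_to_bfi(self, bfi, mu_sp, n_r, lam):
        opt = ph.OpticalProperties(mu_a=0.01, mu_s_prime=mu_sp, n_r=n_r, lambda0=lam)
        slope = ph.decay_rate_line(1.0, bfi, opt, 0.0)  # xi at 1 ps == slope per ps
        assert ph.bfi_from_slope(slope, opt) == pytest.approx(bfi, rel=1e-9)

    def test_zero_at_intercept(self, optics):
        assert ph.decay_rate_line(57.8, 1e-8, optics, 57.8) == 0.0

    def test_linearity_in_slope(self, optics):
        s = ph.decay_rate_line(1.0, 1e-8, optics, 0.0)
        assert ph.bfi_from_slope(2 * s, optics) == pytest.approx(
            2 * ph.bfi_from_slope(s, optics), rel=1e-12
        )

    def test_zero_mu_s_prime_rejected(self, optics):
        with pytest.raises(ZeroDivisionError):
            bad = ph.OpticalProperties(mu_a=0.0, mu_s_prime=1.0)
            object.__setattr__(bad, "mu_s_prime", 0.0)
            ph.bfi_from_slope(1.0, bad)


class TestTPSF:
    def test_absorption_factorizes(self, optics):
        tau = np.linspace(50, 2000, 50)
        opt0 = ph.OpticalProperties(mu_a=0.0, mu_s_prime=10.0, n_r=1.33, lambda0=855.0)
        ratio = ph.tpsf_semi_infinite(tau, 0.76, optics) / ph.tpsf_semi_infinite(tau, 0.76, opt0)
        np.testing.assert_allclose(
            ratio, np.exp(-optics.mu_a * C_CM_S * tau * PS / optics.n_r), rtol=1e-12
        )

    def test_late_log_slope_approaches_absorption_rate(self, optics):
        # dominant exponential: log slope -> -mu_a c/n_r - (5/2)/t at late TOF
        t1, t2 = 2.0e5, 2.1e5  # ps
        y1, y2 = ph.tpsf_semi_infinite(t1, 0.76, optics), ph.tpsf_semi_infinite(t2, 0.76, optics)
        slope = (np.log(y2) - np.log(y1)) / ((t2 - t1) * PS)
        t_mid = 0.5 * (t1 + t2) * PS
        expected = -optics.mu_a * C_CM_S / optics.n_r - 2.5 / t_mid
        assert slope == pytest.approx(expected, rel=0.005)

    def test_peak_location_matches_grid_search(self, optics):
        tau = np.linspace(1.0, 1000.0, 200000)
        y = ph.tpsf_semi_infinite(tau, 0.76, optics)
        t_peak = tau[np.argmax(y)]  # brute-force oracle over the closed form
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda t: -ph.tpsf_semi_infinite(t, 0.76, optics), bounds=(1, 1000), method="bounded"
        )
        assert res.x == pytest.approx(t_peak, abs=0.1)

    def test_strictly_positive_and_vanishing_at_extremes(self, optics):
        tau = np.linspace(1.0, 5000.0, 100)
        y = ph.tpsf_semi_infinite(tau, 0.76, optics)
        assert np.all(y > 0)
        assert ph.tpsf_semi_infinite(0.01, 0.76, optics) < y.max() * 1e-10
        assert ph.tpsf_semi_infinite(1e6, 0.76, optics) < y.max() * 1e-10

    def test_nonpositive_tof_rejected(self, optics):
        with pytest.raises(ValueError):
            ph.tpsf_semi_infinite(0.0, 0.76, optics)


class TestIRF:
    def test_rect_window_fwhm_is_sinc_squared_width(self):
        # numeric FWHM of sinc^2: 0.886/delta_nu = 13.7 ps at 64.7 GHz
        irf = ph.irf_profile(64.7, "rect")
        assert irf.fwhm_ps == pytest.approx(0.886 / 64.7e9 / PS, rel=0.01)

    def test_hann_window_fwhm(self):
        irf = ph.irf_profile(64.7, "hann")
        assert irf.fwhm_ps == pytest.approx(1.44 / 64.7e9 / PS, rel=0.01)

    def test_halving_tuning_range_doubles_fwhm(self):
        a = ph.irf_profile(64.7, "hann")
        b = ph.irf_profile(32.35, "hann", tof_span_ps=800.0)
        assert b.fwhm_ps == pytest.approx(2 * a.fwhm_ps, rel=1e-3)

    def test_unknown_window_rejected(self):
        with pytest.raises(KeyError):
            ph.irf_profile(64.7, "kaiser-nope")

    def test_profile_normalized_nonnegative(self):
        irf = ph.irf_profile(64.7, "hamming")
        assert irf.profile.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(irf.profile >= 0)


class TestConvolveIRF:
    def _delta(self, shift_bins=0, step=0.5):
        tof = np.arange(-20, 20.5, step)
        prof = np.zeros_like(tof)
        prof[np.argmin(np.abs(tof - shift_bins * step))] = 1.0
        return ph.IRFModel(tof_axis=tof, profile=prof)

    def test_delta_is_identity(self):
        grid = np.arange(0, 200, 0.5)
        curve = np.exp(-(((grid - 60) / 15.0) ** 2))
        out = ph.convolve_irf(curve, grid, self._delta())
        np.testing.assert_allclose(out, curve, atol=1e-14)

    def test_sum_preserved_for_unit_sum_irf(self):
        grid = np.arange(0, 400, 0.5)
        curve = np.exp(-(((grid - 200) / 20.0) ** 2))
        irf = ph.gaussian_irf(22.0, tof_span_ps=100.0, tof_step_ps=0.5)
        out = ph.convolve_irf(curve, grid, irf)
        assert out.sum() == pytest.approx(curve.sum(), rel=1e-9)
        assert np.all(out >= 0)

    def test_shifted_irf_shifts_output(self):
        grid = np.arange(0, 200, 0.5)
        curve = np.exp(-(((grid - 100) / 10.0) ** 2))
        out0 = ph.convolve_irf(curve, grid, self._delta(0))
        out5 = ph.convolve_irf(curve, grid, self._delta(5))
        np.testing.assert_allclose(out5[5:], out0[:-5], atol=1e-14)

    def test_grid_mismatch_rejected(self):
        grid = np.arange(0, 100, 1.0)
        irf = ph.gaussian_irf(22.0, tof_step_ps=0.5)
        with pytest.raises(ValueError):
            ph.convolve_irf(np.ones_like(grid), grid, irf)
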