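"""Correlation-transport Monte Carlo: samplers, walks, path statistics."""

import numpy as np
import pytest

from inirs import montecarlo as mc
from inirs._constants import C_CM_S, PS
from inirs.physics import MSDModel, OpticalProperties, tpsf_semi_infinite


class TestPhaseFunctions:
    def test_isotropic_hg_is_uniform_in_cos_theta(self):
        rng = np.random.default_rng(0)
        s = mc.phase_function_variants("henyey_greenstein", 0.0)
        draws = s.sample(200_000, rng)
        # uniform on [-1, 1]: mean 0, variance 1/3
        assert draws.mean() == pytest.approx(0.0, abs=3 * np.sqrt(1 / 3 / 200_000))
        assert draws.var() == pytest.approx(1 / 3, rel=0.02)

    @pytest.mark.parametrize("g", [0.6, 0.975])
    def test_hg_empirical_mean_cosine(self, g):
        rng = np.random.default_rng(1)
        s = mc.phase_function_variants("henyey_greenstein", g)
        draws = s.sample(1_000_000, rng)
        se = draws.std() / 1000.0
        assert draws.mean() == pytest.approx(g, abs=3 * se)

    def test_two_term_hg_mixture_mean_matches_closed_form(self):
        rng = np.random.default_rng(2)
        s = mc.phase_function_variants("two_term_hg", 0.92, g_backward=-0.3, weight=0.9)
        assert s.mean_cosine == pytest.approx(0.9 * 0.92 + 0.1 * (-0.3))
        draws = s.sample(1_000_000, rng)
        se = draws.std() / 1000.0
        assert draws.mean() == pytest.approx(s.mean_cosine, abs=3 * se)

    def test_invalid_g_rejected(self):
        with pytest.raises(ValueError):
            mc.phase_function_variants("henyey_greenstein", 1.0)
        with pytest.raises(ValueError):
            mc.phase_function_variants("nope", 0.5)


class TestSimulatePaths:
    def test_no_absorption_gives_unit_weights(self, optics):
        opt0 = OpticalProperties(mu_a=0.0, mu_s_prime=10.0, n_r=1.33, lambda0=855.0)
        layer = mc.MediumLayer(
            thickness=np.inf, optics=opt0, dynamic_fraction=1.0,
            msd_model=MSDModel(kind="brownian", D_B=1e-8),
        )
        ens = mc.simulate_paths([layer], mc.DetectionGeometry(radius=0.3), 5000, seed=3)
        assert len(ens) > 0
        np.testing.assert_allclose(ens.weight, 1.0)

    def test_no_dynamic_fraction_gives_zero_dynamic_events(self, optics):
        layer = mc.MediumLayer(thickness=np.inf, optics=optics, dynamic_fraction=0.0)
        ens = mc.simulate_paths([layer], mc.DetectionGeometry(radius=0.3), 5000, seed=3)
        assert np.all(ens.n_dynamic == 0)
        assert np.all(ens.q2_sum == 0)

    def test_reproducible_for_fixed_seed(self, optics):
        layer = mc.MediumLayer(thickness=np.inf, optics=optics, dynamic_fraction=1.0,
                               msd_model=MSDModel(kind="brownian", D_B=1e-8))
        a = mc.simulate_paths([layer], mc.DetectionGeometry(radius=0.3), 3000, seed=9)
        b = mc.simulate_paths([layer], mc.DetectionGeometry(radius=0.3), 3000, seed=9)
        np.testing.assert_array_equal(a.tof_ps, b.tof_ps)
        np.testing.assert_array_equal(a.q2_sum, b.q2_sum)

    def test_tof_equals_path_length_times_index_over_c(self, ens_homogeneous):
        tof_expected = ens_homogeneous.path_length.sum(axis=1) * 1.33 / C_CM_S / PS
        np.testing.assert_allclose(ens_homogeneous.tof_ps, tof_expected, rtol=1e-9)

    def test_q2_bounded_by_backscatter_maximum(self, ens_homogeneous, optics):
        # each event obeys q^2 <= 4 k^2; sums are bounded by count * max
        qmax = 4 * optics.k**2
        # per-path average per dynamic event must respect the bound
        have = ens_homogeneous.n_dynamic > 0
        per_event = ens_homogeneous.q2_sum.sum(axis=1)[have] / ens_homogeneous.n_dynamic[have]
        assert np.all(per_event <= qmax + 1e-6)

    def test_mean_detected_tof_matches_diffusion_oracle(self, optics):
        # annular detection at rho = 0.76 cm vs TPSF-weighted mean (5% MC tolerance)
        layer = mc.MediumLayer(thickness=np.inf, optics=optics, dynamic_fraction=1.0,
                               msd_model=MSDModel(kind="brownian", D_B=1e-8))
        geo = mc.DetectionGeometry(rho=0.76, radius=0.1)
        ens = mc.simulate_paths([layer], geo, 600_000, seed=21, max_tof_ps=3000.0)
        assert len(ens) > 500
        # compare above 100 ps where the diffusion approximation holds
        sel = ens.tof_ps >= 100.0
        mc_mean = np.average(ens.tof_ps[sel], weights=ens.weight[sel])
        tau = np.linspace(100.0, 3000.0, 6000)
        tpsf = tpsf_semi_infinite(tau, 0.76, optics)
        oracle = np.average(tau, weights=tpsf)
        assert mc_mean == pytest.approx(oracle, rel=0.05)

    def test_bad_config_rejected(self, optics):
        layer = mc.MediumLayer(thickness=np.inf, optics=optics)
        with pytest.raises(ValueError):
            mc.simulate_paths([], mc.DetectionGeometry(), 100)
        with pytest.raises(ValueError):
            mc.simulate_paths([layer], mc.DetectionGeometry(), 0)
        with pytest.raises(ValueError):
            mc.MediumLayer(thickness=-1.0, optics=optics)


class TestAutocorrelationFromPaths:
    def test_zero_lag_equals_tpsf(self, ens_homogeneous):
        taud = np.array([0.0, 1e-5, 1e-4])
        edges = np.arange(0.0, 1500.0 + 22, 22.0)
        _, G1, tpsf = mc.autocorrelation_from_paths(
            ens_homogeneous, [MSDModel(kind="brownian", D_B=1.18e-8)], taud, edges
        )
        ok = np.isfinite(tpsf)
        np.testing.assert_allclose(G1[ok, 0], tpsf[ok], rtol=1e-12)

    def test_all_static_medium_keeps_tpsf_at_all_lags(self, optics):
        layer = mc.MediumLayer(thickness=np.inf, optics=optics, dynamic_fraction=0.0)
        ens = mc.simulate_paths([layer], mc.DetectionGeometry(radius=0.3), 20_000, seed=3)
        taud = np.linspace(0, 1e-2, 5)
        edges = np.arange(0.0, ens.tof_ps.max() + 22, 22.0)
        _, G1, tpsf = mc.autocorrelation_from_paths(
            ens, [MSDModel(kind="brownian", D_B=1e-8)], taud, edges
        )
        ok = np.isfinite(tpsf)
        for m in range(len(taud)):
            np.testing.assert_allclose(G1[ok, m], tpsf[ok], rtol=1e-12)

    def test_empty_bins_are_nan_not_zero(self, ens_homogeneous):
        taud = np.array([0.0, 1e-5])
        edges = np.arange(0.0, 4000.0, 22.0)  # extends far beyond max TOF
        _, G1, tpsf = mc.autocorrelation_from_paths(
            ens_homogeneous, [MSDModel(kind="brownian", D_B=1e-8)], taud, edges
        )
        assert np.isnan(tpsf[-1]) and np.all(np.isnan(G1[-1]))

    def test_uncovered_range_rejected(self, ens_homogeneous):
        with pytest.raises(ValueError):
            mc.autocorrelation_from_paths(
                ens_homogeneous, [MSDModel(kind="brownian", D_B=1e-8)],
                np.array([0.0]), np.array([100.0, 200.0]),
            )

    def test_pointwise_agreement_with_dws_solution(self, ens_homogeneous, optics):
        """Normalized MC autocorrelations match the diffusing-wave
        closed form pointwise at TOFs well beyond the mean free time."""
        from inirs.physics import g1_dws

        model = MSDModel(kind="brownian", D_B=1.18e-8)
        taud = np.linspace(0, 50e-6, 11)
        edges = np.arange(0.0, 1500.0 + 22, 22.0)
        cent, G1, tpsf = mc.autocorrelation_from_paths(ens_homogeneous, [model], taud, edges)
        counts = np.bincount(
            np.clip(np.digitize(ens_homogeneous.tof_ps, edges) - 1, 0, len(cent) - 1),
            minlength=len(cent),
        )
        mean_free_time_ps = optics.n_r / (optics.mu_s_prime * C_CM_S) / PS
        sel = (counts > 500) & (cent > 5 * mean_free_time_ps)
        assert sel.sum() >= 10
        for b in np.where(sel)[0]:
            g_mc = G1[b] / tpsf[b]
            g_th = g1_dws(cent[b], taud, optics, model)
            # binomial-style standard error of the weighted mean factor
            se = np.sqrt(np.maximum(g_mc * (1 - g_mc), 1e-8) / counts[b])
            assert np.all(np.abs(g_mc - g_th) <= np.maximum(3 * se, 0.01))


class TestFilterPaths:
    def test_threshold_pi_is_identity(self, ens_tissue_like):
        out = mc.filter_paths(ens_tissue_like, np.pi)
        assert len(out) == len(ens_tissue_like)

    def test_threshold_zero_keeps_only_paths_without_dynamic_events(self, ens_tissue_like):
        out = mc.filter_paths(ens_tissue_like, 0.0)
        assert np.all(out.max_dynamic_angle == 0.0)

    def test_retained_fraction_decreases_with_tof(self, ens_tissue_like):
        """Forward-scattered-only (dynamical snake) paths thin out with
        TOF, but remain probable to intermediate TOFs."""
        filt = mc.filter_paths(ens_tissue_like, np.pi / 6)
        edges = np.arange(0.0, 1000.0 + 44, 44.0)
        idx_a = np.clip(np.digitize(ens_tissue_like.tof_ps, edges) - 1, 0, len(edges) - 2)
        idx_f = np.clip(np.digitize(filt.tof_ps, edges) - 1, 0, len(edges) - 2)
        na = np.bincount(idx_a, minlength=len(edges) - 1)
        nf = np.bincount(idx_f, minlength=len(edges) - 1)
        good = na > 1000
        frac = nf[good] / na[good]
        centers = 0.5 * (edges[:-1] + edges[1:])[good]
        slope = np.polyfit(centers, frac, 1)[0]
        assert slope < 0
        assert frac[0] > frac[-1]
        # such paths remain probable at intermediate TOF
        assert frac[-1] > 0.5
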