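"""Multiscale GWR: back-fitting, ENP decomposition, corrected inference,
Monte Carlo non-stationarity test."""

import numpy as np
import pytest
from scipy import optimize, stats

from mgwrlab import (
    KernelSpec,
    MGWROptions,
    SyntheticConfig,
    bump,
    constant,
    corrected_critical_t,
    default_config,
    fit_gwr,
    fit_mgwr,
    fit_ols,
    monte_carlo_test,
    simulate_dataset,
    soc_f,
)
from mgwrlab.dimensions import scalability_class
from mgwrlab.exceptions import ConfigError


class TestSOCF:
    def test_identical_is_zero(self):
        v = np.array([1.0, -2.0, 3.0])
        assert soc_f(v, v) == 0.0

    def test_closed_form_half(self):
        assert soc_f(np.array([1.0, 1.0]), np.array([2.0, 2.0])) == pytest.approx(0.5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        perm = rng.permutation(20)
        assert soc_f(a, b) == pytest.approx(soc_f(a[perm], b[perm]))

    def test_zero_current_uses_absolute_form(self):
        prev = np.array([1.0, 1.0])
        assert soc_f(prev, np.zeros(2)) == pytest.approx(1.0)


class TestCorrectedCriticalT:
    def test_no_correction_at_enp_one(self):
        assert corrected_critical_t(0.05, 1.0, 100) == pytest.approx(
            stats.t.ppf(0.975, 100)
        )

    def test_monotone_in_enp(self):
        vals = [corrected_critical_t(0.05, e, 500) for e in (1.0, 2.0, 5.0, 20.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_matches_numerical_cdf_inversion(self):
        """Oracle: invert the t CDF numerically with a root finder."""
        target = 1.0 - 0.05 / 2.0 / 2.0  # alpha=0.05, enp=2, upper tail
        oracle = optimize.brentq(lambda t: stats.t.cdf(t, 1000) - target, 0, 50)
        assert corrected_critical_t(0.05, 2.0, 1000) == pytest.approx(oracle, abs=1e-8)

    def test_subunit_enp_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            v = corrected_critical_t(0.05, 0.4, 100)
        assert v == pytest.approx(stats.t.ppf(0.975, 100))


def _all_constant_config(n=400, seed=11):
    return SyntheticConfig(
        n_units=n, n_covariates=2, correlation=0.2,
        surfaces={"intercept": constant(0.1), "x1": constant(0.5),
                  "x2": constant(-0.3)},
        noise_sd=0.5, seed=seed,
    )


class TestFitMGWR:
    def test_all_constant_surfaces_go_global(self):
        data, _ = simulate_dataset(_all_constant_config())
        res = fit_mgwr(data)
        ols = fit_ols(data)
        assert np.all(res.bandwidths[1:] >= 0.9 * data.n)
        for j in (1, 2):
            assert abs(res.params[:, j].mean() - ols.coefficients[j]) < 0.05

    def test_mixed_scales_separate_bandwidths(self):
        cfg = SyntheticConfig(
            n_units=300, n_covariates=2, correlation=0.2,
            surfaces={"intercept": constant(0.1), "x1": constant(0.5),
                      "x2": bump(35.0, 35.0, radius=40.0, height=2.0, baseline=0.0)},
            noise_sd=0.5, seed=11,
        )
        data, _ = simulate_dataset(cfg)
        res = fit_mgwr(data)
        assert res.bandwidths[1] > res.bandwidths[2]

    def test_backfit_solution_is_a_fixed_point(self):
        """At convergence, refitting any single term against its partial
        residual leaves the solution unchanged (the defining property of
        the back-fitting estimate)."""
        from mgwrlab.gwr import distance_matrix
        from mgwrlab.mgwr import _TermSmoothers

        cfg = SyntheticConfig(
            n_units=150, n_covariates=1, correlation=np.eye(1),
            surfaces={"intercept": constant(0.2),
                      "x1": bump(40.0, 40.0, radius=40.0, height=2.0, baseline=0.0)},
            noise_sd=0.5, seed=7,
        )
        data, _ = simulate_dataset(cfg)
        res = fit_mgwr(data, MGWROptions(tol=1e-10, max_iter=500))
        std = data.standardized()
        sm = _TermSmoothers(distance_matrix(std.units))
        F = std.X * res.params
        for j in range(std.X.shape[1]):
            e = std.y - F.sum(axis=1) + F[:, j]
            refit = sm.fit_term(std.X[:, j], e, int(res.bandwidths[j]))
            assert np.allclose(refit, res.params[:, j], atol=1e-6)

    def test_shared_bandwidth_tracks_joint_gwr(self):
        """With every term forced to one common bandwidth the additive fit
        closely tracks the one-shot GWR calibration (the fixed points
        differ only through smoother coupling between units)."""
        cfg = SyntheticConfig(
            n_units=150, n_covariates=1, correlation=np.eye(1),
            surfaces={"intercept": constant(0.2),
                      "x1": bump(40.0, 40.0, radius=40.0, height=2.0, baseline=0.0)},
            noise_sd=0.5, seed=7,
        )
        data, _ = simulate_dataset(cfg)
        k = 60
        res_m = fit_mgwr(data, MGWROptions(tol=1e-9, bw_min=k, bw_max=k, max_iter=500))
        res_g = fit_gwr(data, KernelSpec(k_neighbors=k))
        assert np.corrcoef(res_m.params[:, 1], res_g.params[:, 1])[0, 1] > 0.99
        assert np.corrcoef(res_m.fitted, res_g.fitted)[0, 1] > 0.99
        assert np.mean(np.abs(res_m.fitted - res_g.fitted)) < 0.1

    def test_enp_decomposition(self, preset_mgwr):
        assert preset_mgwr.enp.sum() == pytest.approx(
            preset_mgwr.trace_s, rel=1e-6
        )

    def test_convergence_trace_decreases(self, preset_mgwr):
        soc = preset_mgwr.soc_history
        assert preset_mgwr.converged
        assert soc[-1] < soc[0]
        assert soc[-1] < 1e-5

    def test_parameter_recovery_rmse(self, preset_mgwr, preset_truth_standardized):
        rmse = np.sqrt(
            np.mean((preset_mgwr.params - preset_truth_standardized) ** 2, axis=0)
        )
        # gradient and constant terms recover tightly; bump terms carry the
        # smoothing bias/variance floor of the preset conditions
        assert np.all(rmse < 0.2)
        assert np.all(rmse[:5] < 0.1)

    def test_scale_class_recovery_across_replicates(self):
        """Constant -> global, gradient -> regional, bump -> local bandwidth
        classes recovered in >= 8/10 seeded replicates per scale."""
        expected = {"x1": "global", "x2": "global", "x3": "regional",
                    "x4": "regional", "x5": "local", "x6": "local"}
        hits = {"global": 0, "regional": 0, "local": 0}
        total = {"global": 0, "regional": 0, "local": 0}
        n_rep = 10
        for seed in range(100, 100 + n_rep):
            data, _ = simulate_dataset(default_config(seed=seed))
            res = fit_mgwr(data)
            for j, nm in enumerate(res.names):
                if nm in expected:
                    want = expected[nm]
                    total[want] += 1
                    got = scalability_class(int(res.bandwidths[j]), data.n)
                    hits[want] += got == want
        for scale in hits:
            assert hits[scale] / total[scale] >= 0.8, (scale, hits, total)

    def test_aicc_beats_ols_on_heterogeneous_data(self, preset_mgwr, preset_ols):
        assert preset_mgwr.aicc < preset_ols.aicc

    def test_se_positive_and_critical_t_ordered(self, preset_mgwr):
        assert np.all(preset_mgwr.se > 0)
        plain = stats.t.ppf(0.975, 400 - preset_mgwr.trace_s)
        assert np.all(preset_mgwr.critical_t >= plain - 1e-12)

    def test_too_many_terms_rejected(self):
        data, _ = simulate_dataset(_all_constant_config(n=400))
        data2, _ = simulate_dataset(_all_constant_config(n=400))
        with pytest.raises(ConfigError):
            fit_mgwr(data, MGWROptions(bw_min=500))


@pytest.fixture(scope="module")
def mixed_fit():
    cfg = SyntheticConfig(
        n_units=150, n_covariates=2, correlation=0.2,
        surfaces={"intercept": constant(0.3), "x1": constant(0.4),
                  "x2": bump(40.0, 40.0, radius=35.0, height=3.0, baseline=0.0)},
        noise_sd=0.5, seed=11,
    )
    data, _ = simulate_dataset(cfg)
    return data, fit_mgwr(data)


class TestMonteCarlo:
    def test_pvalue_lower_bound(self, mixed_fit):
        data, res = mixed_fit
        mc = monte_carlo_test(data, res, n_perm=19, seed=1)
        assert np.all(mc.pvalues >= 1.0 / 20.0)
        assert np.all(mc.pvalues <= 1.0)

    def test_detects_bump_not_constant(self, mixed_fit):
        data, res = mixed_fit
        mc = monte_carlo_test(data, res, n_perm=99, seed=2)
        p = dict(zip(mc.names, mc.pvalues))
        assert p["x2"] <= 0.05      # strongly non-stationary term
        assert p["x1"] > 0.05       # stationary term

    def test_seed_determinism(self, mixed_fit):
        data, res = mixed_fit
        a = monte_carlo_test(data, res, n_perm=29, seed=3)
        b = monte_carlo_test(data, res, n_perm=29, seed=3)
        assert np.array_equal(a.pvalues, b.pvalues)

    def test_too_few_permutations_rejected(self, mixed_fit):
        data, res = mixed_fit
        with pytest.raises(ConfigError):
            monte_carlo_test(data, res, n_perm=10)
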