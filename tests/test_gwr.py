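"""GWR engine: distances, kernel, local WLS, hat matrix, bandwidth search."""

import numpy as np
import pytest

from mgwrlab import (
    KernelSpec,
    SyntheticConfig,
    adaptive_bisquare,
    bump,
    constant,
    distance_matrix,
    fit_gwr,
    local_fit,
    select_bandwidth,
    simulate_dataset,
)
from mgwrlab.exceptions import ConfigError, LocalSingularityError
from mgwrlab.gwr import golden_section_integers, kernel_weights


def _bump_config(n=400, seed=11, height=2.0):
    return SyntheticConfig(
        n_units=n, n_covariates=1, correlation=np.eye(1),
        surfaces={"intercept": constant(0.2),
                  "x1": bump(35.0, 35.0, radius=40.0, height=height, baseline=0.0)},
        noise_sd=0.5, seed=seed,
    )


def _constant_config(n=150, seed=11):
    return SyntheticConfig(
        n_units=n, n_covariates=1, correlation=np.eye(1),
        surfaces={"intercept": constant(0.2), "x1": constant(0.6)},
        noise_sd=0.5, seed=seed,
    )


class TestDistances:
    def test_euclidean_345(self):
        D = distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 0] == 0.0
        assert D[0, 1] == pytest.approx(5.0)
        assert D[1, 0] == pytest.approx(5.0)

    def test_haversine_zero_and_known_arc(self):
        # one degree of longitude on the equator is ~111.195 km
        D = distance_matrix(np.array([[10.0, 0.0], [10.0, 0.0], [11.0, 0.0]]), "haversine")
        assert D[0, 1] == 0.0
        assert D[0, 2] == pytest.approx(111.195, abs=0.01)

    def test_triangle_inequality(self):
        coords = np.random.default_rng(0).uniform(0, 10, (20, 2))
        D = distance_matrix(coords)
        for i in range(20):
            for j in range(20):
                assert D[i, j] <= D[i, 5] + D[5, j] + 1e-9

    def test_unknown_metric(self):
        with pytest.raises(ConfigError):
            distance_matrix(np.zeros((3, 2)), "manhattan")


class TestAdaptiveBisquare:
    def test_closed_forms(self):
        d = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        w = adaptive_bisquare(d, k_neighbors=4)  # b = 4
        assert w[0] == 1.0               # self distance 0
        assert w[3] == 0.0               # at the support boundary
        assert w[2] == pytest.approx((1 - 0.25) ** 2)  # d = b/2 -> 0.5625
        assert w[4] == 0.0

    def test_exactly_k_nonzero_without_ties(self):
        rng = np.random.default_rng(1)
        d = np.concatenate([[0.0], rng.uniform(1, 10, 29)])
        for k in (3, 7, 15):
            w = adaptive_bisquare(d, k)
            # the k-th nearest sits exactly at b and gets weight zero,
            # leaving the self unit plus k-2 interior neighbors nonzero
            assert np.count_nonzero(w) == k - 1

    def test_small_k_rejected(self):
        with pytest.raises(ConfigError):
            adaptive_bisquare(np.array([0.0, 1.0, 2.0]), 1)


class TestLocalFit:
    def test_unit_weights_equal_ols(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(40), rng.standard_normal((40, 2))])
        y = rng.standard_normal(40)
        beta, _ = local_fit(X, y, np.ones(40), focal=0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(beta, ols, atol=1e-10)

    def test_intercept_only_is_weighted_mean(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(30)
        w = rng.uniform(0.1, 1.0, 30)
        beta, _ = local_fit(np.ones((30, 1)), y, w, focal=0)
        assert beta[0] == pytest.approx(np.sum(w * y) / np.sum(w))

    def test_brute_force_normal_equations(self):
        """Independent oracle: assemble X'WX and X'Wy element by element
        with explicit loops and solve the 3x3 system."""
        rng = np.random.default_rng(4)
        n, p = 12, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        y = rng.standard_normal(n)
        w = rng.uniform(0.05, 1.0, n)
        A = np.zeros((p, p))
        b = np.zeros(p)
        for a_ in range(p):
            for c in range(p):
                A[a_, c] = sum(X[m, a_] * w[m] * X[m, c] for m in range(n))
            b[a_] = sum(X[m, a_] * w[m] * y[m] for m in range(n))
        expected = np.linalg.solve(A, b)
        beta, lev = local_fit(X, y, w, focal=5)
        assert np.allclose(beta, expected, atol=1e-10)
        # leverage row applied to y reproduces the focal fitted value
        assert lev @ y == pytest.approx(X[5] @ beta)

    def test_too_few_neighbors_raises(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        w = np.zeros(10)
        w[0] = 1.0
        with pytest.raises(LocalSingularityError):
            local_fit(X, np.arange(10.0), w, focal=0)


@pytest.fixture(scope="module")
def bump_fit():
    data, truth = simulate_dataset(_bump_config())
    return data, truth, fit_gwr(data, KernelSpec(k_neighbors=50))


class TestFitGWR:
    def test_fitted_is_rowwise_product(self, bump_fit):
        data, _, res = bump_fit
        std = data.standardized()
        assert np.allclose(res.fitted, np.sum(std.X * res.params, axis=1), atol=1e-10)

    def test_recovers_bump_surface(self, bump_fit):
        data, truth, res = bump_fit
        truth_std = truth.beta[:, 1] / data.y.std(ddof=1)
        assert np.corrcoef(res.params[:, 1], truth_std)[0, 1] > 0.8

    def test_hat_trace_two_ways(self, bump_fit):
        """tr(S) from the stored diagonal matches per-row leverage inner
        products recomputed independently."""
        data, _, res = bump_fit
        std = data.standardized()
        D = distance_matrix(std.units)
        W = kernel_weights(D, 50)
        trace = 0.0
        for i in range(std.n):
            _, lev = local_fit(std.X, std.y, W[i], focal=i)
            trace += lev[i]
            assert lev @ std.y == pytest.approx(res.fitted[i], abs=1e-8)
        assert trace == pytest.approx(res.trace_s, abs=1e-8)

    def test_full_bandwidth_constant_surface_is_flat(self):
        data, _ = simulate_dataset(_constant_config())
        res = fit_gwr(data, KernelSpec(k_neighbors=data.n))
        assert res.params[:, 1].std() < 0.02

    def test_local_r2_bounded(self, bump_fit):
        _, _, res = bump_fit
        assert np.all(res.local_r2 <= 1.0)

    def test_roughness_monotone_in_bandwidth(self):
        data, _ = simulate_dataset(_bump_config(n=200))
        variances = []
        for k in (25, 50, 100, 150, 200):
            res = fit_gwr(data, KernelSpec(k_neighbors=k))
            variances.append(res.params.var(axis=0).sum())
        for a, b in zip(variances, variances[1:]):
            assert b <= a * 1.05  # non-increasing up to small numerical slack

    def test_invalid_kernel(self):
        data, _ = simulate_dataset(_constant_config())
        with pytest.raises(ConfigError):
            fit_gwr(data, KernelSpec(k_neighbors=data.n + 1))


class TestSelectBandwidth:
    def test_constant_surface_prefers_global(self):
        data, _ = simulate_dataset(_constant_config(n=150))
        bw = select_bandwidth(data)
        assert bw >= 0.9 * data.n

    def test_bump_surface_prefers_local(self):
        data, _ = simulate_dataset(_bump_config(n=150, height=3.0))
        bw = select_bandwidth(data)
        assert bw < 0.5 * data.n

    def test_golden_equals_exhaustive_on_convex_profile(self):
        data, _ = simulate_dataset(_bump_config(n=100))
        std = data.standardized()
        from mgwrlab.gwr import _gwr_aicc

        D = distance_matrix(std.units)
        Ds = np.sort(D, axis=1)
        lo, hi = 10, 100
        profile = {k: _gwr_aicc(std, D, Ds, k) for k in range(lo, hi + 1)}
        exhaustive = min(profile, key=lambda k: (profile[k], k))
        golden, _ = golden_section_integers(
            lambda k: _gwr_aicc(std, D, Ds, k), lo, hi, exhaustive_below=2
        )
        assert golden == exhaustive

    def test_empty_range_rejected(self):
        data, _ = simulate_dataset(_constant_config())
        with pytest.raises(ConfigError):
            select_bandwidth(data, bw_min=100, bw_max=50)
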