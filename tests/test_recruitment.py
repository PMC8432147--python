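"""Recruitment weights and cohort sampling: identities, balance, feasibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import selrecruit as sr
from selrecruit.exceptions import (
    DegenerateCovariateError,
    InfeasibleStratumError,
    InvalidParameterError,
)


def _binary_pool(n_plus, n_minus):
    col = np.r_[np.ones(n_plus), -np.ones(n_minus)]
    return sr.PoolTable(pd.DataFrame({"x": col}), [sr.CovariateSpec("x", "binary")])


class TestBinaryWeights:
    def test_balanced_pool_gives_uniform_weights(self):
        w = sr.binary_weights(np.array([1, -1, 1, -1]))
        assert np.allclose(w.rho, 0.25)

    def test_inverse_probability_worked_example(self):
        # p=3/4: unnormalized weights (1/4,1/4,1/4,3/4), c=3/2
        w = sr.binary_weights(np.array([1, 1, 1, -1]))
        assert np.allclose(w.rho, [1 / 6, 1 / 6, 1 / 6, 1 / 2])
        assert w.c == pytest.approx(1.5)
        # single draw is equally likely to return either level
        assert w.rho[:3].sum() == pytest.approx(0.5)

    def test_degenerate_covariate_rejected_with_optin_fallback(self):
        with pytest.raises(DegenerateCovariateError):
            sr.binary_weights(np.array([1, 1]))
        w = sr.binary_weights(np.array([1, 1]), fallback_uniform=True)
        assert np.allclose(w.rho, 0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(1, 999))
    def test_single_draw_balance_identity(self, n_plus):
        """P(draw a +1) = P(draw a -1) = 1/2 exactly, for any p in (0,1)."""
        n = 1000
        col = np.r_[np.ones(n_plus), -np.ones(n - n_plus)]
        w = sr.binary_weights(col)
        assert w.rho.sum() == pytest.approx(1.0, abs=1e-9)
        assert w.rho[:n_plus].sum() == pytest.approx(0.5, abs=1e-9)


class TestContinuousWeights:
    def test_uniform_pool_weights_flat_inside(self):
        x = np.random.default_rng(31).uniform(size=20000)
        d = sr.estimate_density(x)
        w = sr.continuous_weights(d, x)
        inside = (x >= d.x_l) & (x <= d.x_u)
        cv = w.rho[inside].std() / w.rho[inside].mean()
        assert cv < 0.1

    def test_normal_pool_mode_downweighted_tails_maximal(self, normal_pool):
        x = normal_pool.covariates["x"].to_numpy()
        d = sr.estimate_density(x)
        w = sr.continuous_weights(d, x)
        at_mode = w.rho[np.argmin(np.abs(x))]
        near_lower = w.rho[np.argmin(np.abs(x - d.x_l))]
        assert at_mode < near_lower
        outside = (x < d.x_l) | (x > d.x_u)
        # outside the quantile span the unnormalized weight is exactly 1, the max
        assert np.allclose(w.rho[outside], w.rho.max())
        assert w.rho.max() == pytest.approx(1.0 / w.c)

    def test_matches_pointwise_rule_on_grid(self, normal_pool):
        """Oracle: evaluate the weight formula directly at each value."""
        x = normal_pool.covariates["x"].to_numpy()
        d = sr.estimate_density(x)
        w = sr.continuous_weights(d, x)
        raw = np.where(
            (x >= d.x_l) & (x <= d.x_u),
            np.minimum(d.q / (d.c_prime * d.evaluate(x)), 1.0),
            1.0,
        )
        assert np.allclose(w.rho, raw / raw.sum())


class TestProductWeights:
    def test_single_covariate_identity(self):
        w = sr.binary_weights(np.array([1, 1, 1, -1]))
        assert np.allclose(sr.product_weights([w]).rho, w.rho)

    def test_two_balanced_covariates_give_uniform(self):
        a = sr.binary_weights(np.array([1, 1, -1, -1]))
        b = sr.binary_weights(np.array([1, -1, 1, -1]))
        assert np.allclose(sr.product_weights([a, b]).rho, 0.25)

    def test_constant_factor_drops_out(self):
        # A has p=3/4 (weights non-constant), B is balanced (constant factor)
        A = np.array([1, 1, 1, 1, 1, 1, -1, -1])
        B = np.array([1, -1, 1, -1, 1, -1, 1, -1])
        wa, wb = sr.binary_weights(A), sr.binary_weights(B)
        prod = sr.product_weights([wa, wb])
        assert np.allclose(prod.rho, wa.rho)

    def test_mismatched_pools_rejected(self):
        a = sr.binary_weights(np.array([1, -1]))
        b = sr.binary_weights(np.array([1, -1, 1, -1]))
        with pytest.raises(InvalidParameterError):
            sr.product_weights([a, b])


class TestSampleCohort:
    def test_whole_pool(self):
        pool = _binary_pool(3, 1)
        w = sr.binary_weights(pool.covariates["x"].to_numpy())
        cohort = sr.sample_cohort(pool, w, 4, seed=1)
        assert sorted(cohort.indices.tolist()) == [0, 1, 2, 3]

    def test_oversized_cohort_rejected(self):
        pool = _binary_pool(3, 1)
        w = sr.binary_weights(pool.covariates["x"].to_numpy())
        with pytest.raises(InvalidParameterError):
            sr.sample_cohort(pool, w, 5, seed=1)

    def test_single_draw_frequencies_match_weights(self):
        pool = _binary_pool(3, 1)
        w = sr.binary_weights(pool.covariates["x"].to_numpy())  # (1/6,1/6,1/6,1/2)
        draws = 20000
        counts = np.zeros(4)
        for rep in range(draws):
            counts[sr.sample_cohort(pool, w, 1, seed=rep).indices[0]] += 1
        res = stats.chisquare(counts, f_exp=w.rho * draws)
        assert res.pvalue > 0.001

    def test_mean_cohort_fraction_near_half(self, skewed_binary_pool):
        """In-expectation marginal balance, up to the O(n/N) depletion of the
        minority level inherent to sampling without replacement."""
        w = sr.binary_weights(skewed_binary_pool.covariates["x"].to_numpy())
        fracs = [
            (sr.sample_cohort(skewed_binary_pool, w, 500, seed=s).matrix == 1).mean()
            for s in range(200)
        ]
        assert abs(np.mean(fracs) - 0.5) < 0.02

    def test_cohort_flatter_than_pool(self, normal_pool):
        """Recruited covariate values are closer to uniform between the pool
        quantiles than the pool itself (Kolmogorov-Smirnov distance)."""
        x = normal_pool.covariates["x"].to_numpy()
        d = sr.estimate_density(x)
        w = sr.continuous_weights(d, x)
        span = d.x_u - d.x_l

        def ks_to_uniform(vals):
            inside = vals[(vals >= d.x_l) & (vals <= d.x_u)]
            return stats.kstest(inside, "uniform", args=(d.x_l, span)).statistic

        pool_ks = ks_to_uniform(x)
        cohort_ks = [
            ks_to_uniform(sr.sample_cohort(normal_pool, w, 1000, seed=s).matrix[:, 0])
            for s in range(50)
        ]
        assert np.mean(cohort_ks) < pool_ks


class TestJointlyBalanced:
    def test_exact_quota_per_stratum(self):
        pool = sr.generate_binary_pool(1000, (0.25,) * 4, seed=41)
        cohort = sr.jointly_balanced_sample(pool, 100, seed=2)
        X = cohort.matrix
        for a, b in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            assert np.sum((X[:, 0] == a) & (X[:, 1] == b)) == 25

    def test_deficient_stratum_named(self):
        pool = sr.generate_binary_pool(1000, (0.48, 0.48, 0.03, 0.01), seed=42)
        with pytest.raises(InfeasibleStratumError) as err:
            sr.jointly_balanced_sample(pool, 100, seed=3)
        assert err.value.required == 25
        assert err.value.stratum is not None

    def test_single_covariate_splits_evenly(self):
        pool = _binary_pool(25, 25)
        cohort = sr.jointly_balanced_sample(pool, 10, seed=4)
        assert (cohort.matrix == 1).sum() == 5

    def test_divisibility_required_unless_remainder_mode(self):
        pool = sr.generate_binary_pool(1000, (0.25,) * 4, seed=43)
        with pytest.raises(InvalidParameterError):
            sr.jointly_balanced_sample(pool, 101, seed=5)
        cohort = sr.jointly_balanced_sample(pool, 101, seed=5, allow_remainder=True)
        assert cohort.n == 101


class TestRandomSample:
    def test_whole_pool(self):
        pool = _binary_pool(3, 1)
        assert sr.random_sample(pool, 4, seed=1).n == 4

    def test_oversized_rejected(self):
        with pytest.raises(InvalidParameterError):
            sr.random_sample(_binary_pool(3, 1), 5, seed=1)

    def test_preserves_pool_marginal(self, skewed_binary_pool):
        cohort = sr.random_sample(skewed_binary_pool, 5000, seed=6)
        assert abs((cohort.matrix == 1).mean() - 0.75) < 0.03


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_all_weight_constructions_normalized(seed):
    rng = np.random.default_rng(seed)
    col = rng.choice([-1, 1], size=50, p=[0.3, 0.7])
    if len(np.unique(col)) < 2:
        col[0] = -col[0]
    wb = sr.binary_weights(col)
    x = rng.normal(size=200)
    wc = sr.continuous_weights(sr.estimate_density(x), x)
    assert abs(wb.rho.sum() - 1) < 1e-9
    assert abs(wc.rho.sum() - 1) < 1e-9
    assert abs(sr.product_weights([wb, sr.binary_weights(-col)]).rho.sum() - 1) < 1e-9
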