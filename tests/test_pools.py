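"""Generators: distributional correctness, closed-form checks, reproducibility."""

import numpy as np
import pytest
from scipy import stats

import selrecruit as sr
from selrecruit.exceptions import InvalidDistributionError, InvalidParameterError


class TestBinaryPool:
    def test_cell_frequencies_match_joint(self):
        probs = (0.4, 0.3, 0.2, 0.1)
        pool = sr.generate_binary_pool(10000, probs, seed=5)
        X = pool.matrix
        counts = [
            int(np.sum((X[:, 0] == a) & (X[:, 1] == b)))
            for a, b in ((1, 1), (1, -1), (-1, 1), (-1, -1))
        ]
        res = stats.chisquare(counts, f_exp=np.asarray(probs) * 10000)
        assert res.pvalue > 0.001

    def test_uniform_cells_within_sampling_error(self):
        pool = sr.generate_binary_pool(10000, (0.25,) * 4, seed=6)
        X = pool.matrix
        se4 = 4 * np.sqrt(0.25 * 0.75 / 10000)
        for a, b in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            freq = np.mean((X[:, 0] == a) & (X[:, 1] == b))
            assert abs(freq - 0.25) < se4

    @pytest.mark.parametrize(
        "probs", [(0.5, 0.5, 0.5, -0.5), (0.3, 0.3, 0.3, 0.3), (0.5, 0.5)]
    )
    def test_invalid_distribution_rejected(self, probs):
        with pytest.raises(InvalidDistributionError):
            sr.generate_binary_pool(100, probs, seed=0)


class TestNormalPool:
    def test_default_sigma_puts_quantiles_at_unit(self):
        pool = sr.generate_normal_pool(20000, seed=7)
        x = pool.covariates["x"].to_numpy()
        q05, q95 = np.quantile(x, [0.05, 0.95])
        # MC error of an empirical 5% quantile at N=20000 is ~0.009
        assert abs(q05 - (-1.0)) < 0.05
        assert abs(q95 - 1.0) < 0.05

    def test_mean_converges(self):
        pool = sr.generate_normal_pool(10000, mu=5.0, sigma=1.0, seed=8)
        assert abs(pool.covariates["x"].mean() - 5.0) < 4 / np.sqrt(10000)

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            sr.generate_normal_pool(100, sigma=0.0)

    def test_unit_quantile_sigma_closed_form(self):
        assert round(sr.normal_sigma_for_unit_quantiles(), 3) == 0.608


class TestEHRPool:
    def test_default_marginals_calibrated(self):
        N = 30000
        pool = sr.generate_ehr_pool(N=N, seed=9)
        assert pool.n_covariates == 30
        for name, prev in (("diabetes", 0.154), ("male", 0.572)):
            frac = np.mean(pool.covariates[name].to_numpy() == 1)
            assert abs(frac - prev) < 4 * np.sqrt(prev * (1 - prev) / N)
        # continuous: mean and 5-95 span match the configured summaries
        age = pool.covariates["age"].to_numpy()
        assert abs(age.mean() - 68.1) < 0.3
        q05, q95 = np.quantile(age, [0.05, 0.95])
        assert abs((q95 - q05) - 40.0) < 1.0

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(InvalidParameterError):
            sr.generate_ehr_pool(N=100, prevalences={"a": 1.2}, continuous_params={})


class TestLogisticOutcomes:
    def test_stated_success_probability(self):
        # every individual at x=(+1,+1): p(y=+1) = 1/(1+exp(-1/2))
        X = np.ones((20000, 2))
        model = sr.LogisticModelSpec(w0=-1 / 6, w=(1 / 3, 1 / 3))
        y = sr.simulate_logistic_outcomes(X, model, seed=10)
        p = 1 / (1 + np.exp(-0.5))
        assert abs(np.mean(y == 1) - p) < 4 * np.sqrt(p * (1 - p) / 20000)

    def test_null_model_balanced(self, binary_pool):
        y = sr.simulate_logistic_outcomes(binary_pool, sr.LogisticModelSpec(0.0, (0.0, 0.0)), seed=11)
        assert abs(np.mean(y == 1) - 0.5) < 4 * np.sqrt(0.25 / 10000)

    def test_saturated_intercept(self, binary_pool):
        y = sr.simulate_logistic_outcomes(binary_pool, sr.LogisticModelSpec(10.0, (0.0, 0.0)), seed=12)
        assert np.mean(y == 1) > 0.999

    def test_dimension_mismatch(self, binary_pool):
        with pytest.raises(InvalidParameterError):
            sr.simulate_logistic_outcomes(binary_pool, sr.LogisticModelSpec(0.0, (0.0,)), seed=0)


class TestCoxOutcomes:
    def test_no_censoring_all_events(self, binary_pool):
        model = sr.CoxModelSpec(beta=(0.0, 0.0), baseline_rate=0.1)
        _, events = sr.simulate_cox_outcomes(binary_pool, model, seed=13)
        assert events.mean() == 1.0

    def test_competing_exponentials_event_fraction(self, binary_pool):
        r, c = 0.3, 0.7
        model = sr.CoxModelSpec(beta=(0.0, 0.0), baseline_rate=r, censor_rate=c)
        _, events = sr.simulate_cox_outcomes(binary_pool, model, seed=14)
        expected = r / (r + c)
        assert abs(events.mean() - expected) < 4 * np.sqrt(expected * (1 - expected) / 10000)

    def test_calibrated_censoring_hits_target(self, binary_pool):
        beta = (0.3, -0.2)
        c = sr.calibrate_censoring_rate(binary_pool, beta, 0.05, 0.23)
        model = sr.CoxModelSpec(beta=beta, baseline_rate=0.05, censor_rate=c)
        _, events = sr.simulate_cox_outcomes(binary_pool, model, seed=15)
        assert abs(events.mean() - 0.23) < 4 * np.sqrt(0.23 * 0.77 / 10000)

    def test_admin_horizon_censors(self, binary_pool):
        model = sr.CoxModelSpec(beta=(0.0, 0.0), baseline_rate=0.1, admin_horizon=1.0)
        times, events = sr.simulate_cox_outcomes(binary_pool, model, seed=16)
        assert times.max() <= 1.0
        assert 0 < events.mean() < 1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            sr.CoxModelSpec(beta=(0.0,), baseline_rate=0.0)
        with pytest.raises(InvalidParameterError):
            sr.CoxModelSpec(beta=(0.0,), baseline_rate=0.1, censor_rate=-1.0)


@pytest.mark.parametrize(
    "make",
    [
        lambda seed: sr.generate_binary_pool(500, seed=seed),
        lambda seed: sr.generate_normal_pool(500, seed=seed),
        lambda seed: sr.generate_ehr_pool(500, seed=seed),
    ],
    ids=["binary", "normal", "ehr"],
)
def test_generators_reproducible(make):
    a, b, c = make(42), make(42), make(43)
    assert a.covariates.equals(b.covariates)
    assert not a.covariates.equals(c.covariates)
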