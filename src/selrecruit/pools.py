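"""Synthetic covariate pools and outcome generators.

The recruitment protocols in this package select a cohort of size ``n``
from a pool of ``N`` individuals on the basis of covariates alone.  This
module generates pools with known statistical structure — a two-binary-
covariate pool, a single-normal-covariate pool, and a 30-covariate
EHR-style pool calibrated to published summaries of a UK stable coronary
artery disease registry — together with logistic (binary) and
proportional-hazards (time-to-event) outcome generators, so that every
downstream stage can be exercised and validated without external data.

Binary covariates are coded -1/+1 throughout; continuous covariates are
kept on their natural scale and rescaled to quantile anchors downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    CodingError,
    InvalidDistributionError,
    InvalidParameterError,
)

__all__ = [
    "CovariateSpec",
    "PoolTable",
    "LogisticModelSpec",
    "CoxModelSpec",
    "generate_binary_pool",
    "generate_normal_pool",
    "generate_ehr_pool",
    "simulate_logistic_outcomes",
    "simulate_cox_outcomes",
    "calibrate_censoring_rate",
    "normal_sigma_for_unit_quantiles",
    "EHR_BINARY_PREVALENCES",
    "EHR_CONTINUOUS_PARAMS",
    "DEFAULT_JOINT_PROBS",
]

#: Default joint distribution for the two-binary-covariate pool over the
#: cells ((+1,+1), (+1,-1), (-1,+1), (-1,-1)).  Chosen to be visibly
#: non-uniform so that balancing protocols have something to correct.
DEFAULT_JOINT_PROBS = (0.4, 0.3, 0.2, 0.1)

#: Marginal prevalences (fraction coded +1) for the dichotomous covariates
#: of the EHR-style pool.  "Female" is the complement of "male" and is not
#: generated as a separate column.
EHR_BINARY_PREVALENCES: dict[str, float] = {
    "male": 0.572,
    "imd_high": 0.081,
    "cad_nonspecific": 0.019,
    "unstable_angina": 0.118,
    "nstemi": 0.149,
    "stemi": 0.139,
    "cabg": 0.020,
    "diabetes": 0.154,
    "heart_failure": 0.099,
    "atrial_fibrillation": 0.116,
    "anxiety": 0.120,
    "cancer": 0.080,
    "copd": 0.351,
    "depression": 0.191,
    "renal_disease": 0.066,
    "stroke": 0.054,
    "hypertension": 0.882,
    "long_acting_nitrates": 0.269,
    "peripheral_arterial_disease": 0.070,
    "pci": 0.045,
    "smoking": 0.556,
}

#: (mean, 5th percentile, 95th percentile) for the continuous covariates of
#: the EHR-style pool.  Columns are drawn from a normal distribution whose
#: mean matches the printed mean and whose standard deviation reproduces the
#: printed 5th-95th percentile span.
EHR_CONTINUOUS_PARAMS: dict[str, tuple[float, float, float]] = {
    "age": (68.1, 47.0, 87.0),
    "systolic_bp": (140.5, 110.0, 178.0),
    "diastolic_bp": (79.4, 60.0, 99.6),
    "serum_creatinine": (99.1, 64.8, 148.2),
    "total_cholesterol": (5.2, 3.2, 7.8),
    "hdl_cholesterol": (1.4, 0.8, 2.1),
    "wbc_count": (7.4, 4.5, 11.2),
    "hemoglobin": (13.7, 11.0, 16.6),
    "pulse": (73.0, 51.2, 99.9),
}

_Z95 = stats.norm.ppf(0.95)


def normal_sigma_for_unit_quantiles() -> float:
    """Standard deviation of a zero-mean normal whose 0.05/0.95 quantiles
    are -1 and +1.

    Equals ``1 / Phi^{-1}(0.95) ≈ 0.608``; the conventional scale for a
    single continuous covariate whose quantile anchors are already +-1.
    """
    return 1.0 / _Z95


@dataclass(frozen=True)
class CovariateSpec:
    """Typed description of one covariate column.

    Parameters
    ----------
    name
        Column label.
    kind
        ``"binary"`` (coded -1/+1) or ``"continuous"``.
    coding
        For binary covariates, an optional mapping of the two original
        levels onto -1/+1 (documentation only; generated pools are
        already coded).
    q05_anchor, q95_anchor
        Optional anchors recording the original-scale 0.05/0.95
        quantiles a continuous column was (or should be) scaled by.
    """

    name: str
    kind: str
    coding: dict | None = None
    q05_anchor: float | None = None
    q95_anchor: float | None = None

    def __post_init__(self):
        if self.kind not in ("binary", "continuous"):
            raise InvalidParameterError(
                f"covariate kind must be 'binary' or 'continuous', got {self.kind!r}"
            )


@dataclass
class PoolTable:
    """A pool of N individuals with d typed covariates.

    ``covariates`` is an N x d DataFrame of coded values (binary columns in
    {-1, +1}); ``specs`` carries one :class:`CovariateSpec` per column and
    ``ids`` one identifier per row.
    """

    covariates: pd.DataFrame
    specs: list[CovariateSpec]
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.ids is None:
            self.ids = np.arange(len(self.covariates))
        self.ids = np.asarray(self.ids)
        if self.covariates.shape[0] < 1 or self.covariates.shape[1] < 1:
            raise InvalidParameterError("pool must have N >= 1 rows and d >= 1 columns")
        if len(self.specs) != self.covariates.shape[1]:
            raise InvalidParameterError("one CovariateSpec required per column")
        if self.covariates.isna().any().any():
            raise InvalidParameterError("pool contains missing values")
        for spec in self.specs:
            if spec.kind == "binary":
                vals = np.unique(self.covariates[spec.name].to_numpy())
                if not np.all(np.isin(vals, (-1, 1))):
                    raise CodingError(
                        f"binary covariate {spec.name!r} contains values outside {{-1,+1}}"
                    )

    @property
    def n_individuals(self) -> int:
        return self.covariates.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        return self.covariates.to_numpy(dtype=float)

    def subset(self, indices: np.ndarray) -> "PoolTable":
        """Row-subset of the pool (e.g. one sub-pool of a split)."""
        indices = np.asarray(indices)
        return PoolTable(
            covariates=self.covariates.iloc[indices].reset_index(drop=True),
            specs=list(self.specs),
            ids=self.ids[indices],
        )


@dataclass(frozen=True)
class LogisticModelSpec:
    """Logistic outcome model p(y=+1|x) = 1 / (1 + exp(-w0 - w.x))."""

    w0: float
    w: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "w", tuple(float(v) for v in np.atleast_1d(self.w)))


@dataclass(frozen=True)
class CoxModelSpec:
    """Proportional-hazards generating model.

    Latent event times are exponential with rate
    ``baseline_rate * exp(beta . x)``; independent exponential censoring at
    ``censor_rate`` and administrative censoring at ``admin_horizon``
    compete with the event.
    """

    beta: tuple[float, ...]
    baseline_rate: float
    censor_rate: float = 0.0
    admin_horizon: float = np.inf

    def __post_init__(self):
        object.__setattr__(self, "beta", tuple(float(v) for v in np.atleast_1d(self.beta)))
        if self.baseline_rate <= 0:
            raise InvalidParameterError("baseline_rate must be > 0")
        if self.censor_rate < 0:
            raise InvalidParameterError("censor_rate must be >= 0")
        if self.admin_horizon <= 0:
            raise InvalidParameterError("admin_horizon must be > 0")


# ---------------------------------------------------------------------------
# pool generators
# ---------------------------------------------------------------------------

_BINARY_CELLS = ((1, 1), (1, -1), (-1, 1), (-1, -1))


def generate_binary_pool(
    N: int,
    joint_probs=DEFAULT_JOINT_PROBS,
    seed: int = 0,
) -> PoolTable:
    """Draw N individuals with two binary covariates from an explicit joint
    distribution over the cells ((+1,+1), (+1,-1), (-1,+1), (-1,-1)).
    """
    if N < 1:
        raise InvalidParameterError("N must be >= 1")
    p = np.asarray(joint_probs, dtype=float)
    if p.shape != (4,):
        raise InvalidDistributionError("joint_probs must have exactly 4 cells")
    if np.any(p < 0):
        raise InvalidDistributionError("joint_probs contains a negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise InvalidDistributionError(f"joint_probs sums to {p.sum()}, not 1")
    rng = np.random.default_rng(seed)
    cells = rng.choice(4, size=N, p=p)
    grid = np.asarray(_BINARY_CELLS)
    cov = pd.DataFrame(grid[cells], columns=["x1", "x2"])
    specs = [CovariateSpec("x1", "binary"), CovariateSpec("x2", "binary")]
    return PoolTable(cov, specs)


def generate_normal_pool(
    N: int,
    mu: float = 0.0,
    sigma: float = 0.608,
    seed: int = 0,
) -> PoolTable:
    """Draw N individuals with a single Normal(mu, sigma^2) covariate.

    The default sigma=0.608 makes the population 0.05/0.95 quantiles of a
    zero-mean covariate equal to -1/+1.
    """
    if N < 1:
        raise InvalidParameterError("N must be >= 1")
    if sigma <= 0:
        raise InvalidParameterError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame({"x": rng.normal(mu, sigma, size=N)})
    return PoolTable(cov, [CovariateSpec("x", "continuous")])


def generate_ehr_pool(
    N: int = 82089,
    prevalences: dict[str, float] | None = None,
    continuous_params: dict[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> PoolTable:
    """Generate an EHR-style pool with calibrated marginals.

    Binary columns are Bernoulli at the stated prevalence (coded -1/+1);
    continuous columns are normal with the stated mean and a standard
    deviation reproducing the stated 5th-95th percentile span.  Columns are
    mutually independent: only marginal summaries are calibrated, so the
    correlation structure of a real registry is deliberately absent.
    """
    if N < 1:
        raise InvalidParameterError("N must be >= 1")
    prevalences = EHR_BINARY_PREVALENCES if prevalences is None else prevalences
    continuous_params = (
        EHR_CONTINUOUS_PARAMS if continuous_params is None else continuous_params
    )
    for name, prev in prevalences.items():
        if not 0.0 < prev < 1.0:
            raise InvalidParameterError(
                f"prevalence for {name!r} must be in (0,1), got {prev}"
            )
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    specs: list[CovariateSpec] = []
    for name, prev in prevalences.items():
        columns[name] = np.where(rng.random(N) < prev, 1, -1)
        specs.append(CovariateSpec(name, "binary"))
    for name, (mean, q05, q95) in continuous_params.items():
        if q95 <= q05:
            raise InvalidParameterError(f"q95 must exceed q05 for {name!r}")
        sigma = (q95 - q05) / (2.0 * _Z95)
        columns[name] = rng.normal(mean, sigma, size=N)
        specs.append(CovariateSpec(name, "continuous", q05_anchor=q05, q95_anchor=q95))
    return PoolTable(pd.DataFrame(columns), specs)


# ---------------------------------------------------------------------------
# outcome generators
# ---------------------------------------------------------------------------


def _covariate_matrix(pool) -> np.ndarray:
    X = pool.matrix if isinstance(pool, PoolTable) else np.asarray(pool, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def simulate_logistic_outcomes(pool, model: LogisticModelSpec, seed: int = 0) -> np.ndarray:
    """Draw binary outcomes y in {-1,+1} with p(y=+1|x) = sigmoid(w0 + w.x).

    ``pool`` may be a :class:`PoolTable` or a raw covariate matrix.
    """
    X = _covariate_matrix(pool)
    w = np.asarray(model.w, dtype=float)
    if X.shape[1] != w.shape[0]:
        raise InvalidParameterError(
            f"model has {w.shape[0]} coefficients but pool has {X.shape[1]} covariates"
        )
    eta = model.w0 + X @ w
    p_plus = 1.0 / (1.0 + np.exp(-eta))
    rng = np.random.default_rng(seed)
    return np.where(rng.random(X.shape[0]) < p_plus, 1, -1)


def simulate_cox_outcomes(
    pool, model: CoxModelSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (observed time, event indicator) pairs under the PH model.

    The latent event time is exponential with rate
    ``baseline_rate * exp(beta . x_i)``; the observed time is the minimum of
    the event time, an independent exponential censoring time, and the
    administrative horizon.  The indicator is 1 when the event is observed.
    """
    X = _covariate_matrix(pool)
    beta = np.asarray(model.beta, dtype=float)
    if X.shape[1] != beta.shape[0]:
        raise InvalidParameterError(
            f"model has {beta.shape[0]} coefficients but pool has {X.shape[1]} covariates"
        )
    rng = np.random.default_rng(seed)
    rates = model.baseline_rate * np.exp(X @ beta)
    event_times = rng.exponential(1.0 / rates)
    if model.censor_rate > 0:
        censor_times = rng.exponential(1.0 / model.censor_rate, size=X.shape[0])
    else:
        censor_times = np.full(X.shape[0], np.inf)
    censor_times = np.minimum(censor_times, model.admin_horizon)
    observed = np.minimum(event_times, censor_times)
    events = (event_times <= censor_times).astype(int)
    # guard against zero observed times downstream (exponential draws can
    # underflow to 0.0 only with vanishing probability, but Cox fitters
    # require strictly positive durations)
    observed = np.maximum(observed, np.finfo(float).tiny)
    return observed, events


def calibrate_censoring_rate(
    pool,
    beta,
    baseline_rate: float,
    target_event_fraction: float,
) -> float:
    """Censoring rate making the expected event fraction hit a target.

    With per-individual event rate lambda_i = baseline_rate * exp(beta.x_i)
    and independent exponential censoring at rate c, the probability that
    the event precedes censoring is lambda_i / (lambda_i + c); the expected
    event fraction is its pool average.  Solved for c by bisection.
    """
    if not 0.0 < target_event_fraction < 1.0:
        raise InvalidParameterError("target_event_fraction must be in (0,1)")
    X = _covariate_matrix(pool)
    rates = baseline_rate * np.exp(X @ np.asarray(beta, dtype=float))

    def expected_fraction(c):
        return float(np.mean(rates / (rates + c))) - target_event_fraction

    if target_event_fraction >= 1.0 - 1e-12:
        return 0.0
    lo, hi = 1e-12 * baseline_rate, baseline_rate
    while expected_fraction(hi) > 0:
        hi *= 10.0
        if hi > 1e12 * baseline_rate:
            raise InvalidParameterError("cannot bracket censoring rate")
    return float(optimize.brentq(expected_fraction, lo, hi, xtol=1e-12 * baseline_rate))
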