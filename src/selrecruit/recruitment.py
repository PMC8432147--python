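"""Recruitment probabilities and cohort sampling.

Selective recruitment assigns each pool member a probability of being
invited so that, in expectation, the cohort's covariate distribution is
uniform rather than mirroring the pool:

* binary covariate with pool +1-proportion p: weight proportional to
  (1 - p) for +1 individuals and p for -1 individuals — inverse
  probability weighting, so a single draw is equally likely to return
  either level;
* continuous covariate: weight proportional to q / (c' p_hat(x)) between
  the 0.05 and 0.95 pool quantiles (flattening the density towards the
  uniform height q) and maximal (1 before normalization) outside them;
* several covariates: the row-wise product of the marginal weights,
  renormalized — approximately balancing each marginal.

Cohorts are drawn without replacement by successive weighted draws with
renormalization among the remaining pool, which approximates the target
inclusion probabilities when n << N.  Exact joint balance (equal counts
in every joint stratum of binary covariates) and simple random sampling
are provided as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iter_product

import numpy as np

from .density import BinaryCovariateSummary, DensityEstimate, binary_summary
from .exceptions import (
    DegenerateCovariateError,
    InfeasibleStratumError,
    InvalidParameterError,
)
from .pools import PoolTable

__all__ = [
    "RecruitmentWeights",
    "CohortSample",
    "binary_weights",
    "continuous_weights",
    "product_weights",
    "uniform_weights",
    "sample_cohort",
    "jointly_balanced_sample",
    "random_sample",
]

_SUM_TOL = 1e-9


@dataclass
class RecruitmentWeights:
    """Normalized per-individual recruitment probabilities rho(x_i).

    ``c`` is the normalization constant (the sum of the unnormalized
    weights); ``protocol`` records provenance.
    """

    rho: np.ndarray
    c: float
    protocol: str

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        if np.any(self.rho < 0):
            raise InvalidParameterError("recruitment probabilities must be >= 0")
        if abs(self.rho.sum() - 1.0) > _SUM_TOL:
            raise InvalidParameterError(
                f"recruitment probabilities sum to {self.rho.sum()}, not 1"
            )

    @property
    def n_pool(self) -> int:
        return self.rho.size


@dataclass
class CohortSample:
    """The n individuals selected from a pool, with provenance."""

    indices: np.ndarray
    covariates: "object"  # pandas DataFrame (n x d)
    specs: list
    protocol: str
    seed: int

    @property
    def n(self) -> int:
        return self.indices.size

    @property
    def matrix(self) -> np.ndarray:
        return self.covariates.to_numpy(dtype=float)


def _normalize(raw: np.ndarray, protocol: str) -> RecruitmentWeights:
    c = float(raw.sum())
    if c <= 0:
        raise InvalidParameterError("all unnormalized weights are zero")
    return RecruitmentWeights(rho=raw / c, c=c, protocol=protocol)


def binary_weights(
    values,
    summary: BinaryCovariateSummary | None = None,
    fallback_uniform: bool = False,
) -> RecruitmentWeights:
    """Inverse-probability weights for one -1/+1 covariate.

    Individuals coded +1 get unnormalized weight (1 - p) and individuals
    coded -1 get p, where p is the pool's +1 proportion; normalization
    makes the weights sum to 1.  A degenerate column (p in {0, 1}) is an
    error unless ``fallback_uniform`` explicitly requests uniform weights.
    """
    if summary is None:
        summary = binary_summary(values)
    x = np.asarray(values)
    p = summary.p_plus
    if p in (0.0, 1.0):
        if fallback_uniform:
            return uniform_weights(x.size)
        raise DegenerateCovariateError(
            f"covariate takes a single value (p_plus={p}); weights undefined"
        )
    raw = np.where(x == 1, 1.0 - p, p)
    return _normalize(raw, "binary_marginal")


def continuous_weights(density: DensityEstimate, values) -> RecruitmentWeights:
    """Density-inverse weights for one continuous covariate.

    Unnormalized weight q / (c' p_hat(x_i)) inside [x_l, x_u] — at most 1
    by the definition of c' — and exactly 1 outside, so individuals in the
    thin tails are maximally favoured.
    """
    x = np.asarray(values, dtype=float)
    raw = np.ones_like(x)
    inside = (x >= density.x_l) & (x <= density.x_u)
    raw[inside] = np.minimum(
        density.q / (density.c_prime * density.evaluate(x[inside])), 1.0
    )
    return _normalize(raw, "continuous_marginal")


def product_weights(per_covariate: list[RecruitmentWeights]) -> RecruitmentWeights:
    """Marginal product rule: row-wise product of per-covariate weights,
    renormalized.  Balances each marginal approximately, not exactly."""
    if not per_covariate:
        raise InvalidParameterError("need at least one set of weights")
    sizes = {w.n_pool for w in per_covariate}
    if len(sizes) != 1:
        raise InvalidParameterError("weight vectors cover different pools")
    raw = np.ones(per_covariate[0].n_pool)
    for w in per_covariate:
        raw = raw * w.rho
    return _normalize(raw, "product_marginal")


def uniform_weights(n_pool: int) -> RecruitmentWeights:
    """Uniform 1/N weights (random recruitment)."""
    return RecruitmentWeights(
        rho=np.full(n_pool, 1.0 / n_pool), c=float(n_pool), protocol="random"
    )


def sample_cohort(
    pool: PoolTable,
    weights: RecruitmentWeights,
    n: int,
    seed: int = 0,
) -> CohortSample:
    """Draw n distinct individuals by successive weighted draws without
    replacement (weights renormalized among the remainder at each step)."""
    N = pool.n_individuals
    if weights.n_pool != N:
        raise InvalidParameterError("weights do not match pool size")
    if n > N:
        raise InvalidParameterError(f"cannot recruit n={n} from a pool of N={N}")
    if n > np.count_nonzero(weights.rho > 0):
        raise InvalidParameterError(
            "fewer individuals with positive recruitment probability than n"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(N, size=n, replace=False, p=weights.rho, shuffle=False)
    return CohortSample(
        indices=pool.ids[idx],
        covariates=pool.covariates.iloc[idx].reset_index(drop=True),
        specs=list(pool.specs),
        protocol=weights.protocol,
        seed=seed,
    )


def jointly_balanced_sample(
    pool: PoolTable,
    n: int,
    seed: int = 0,
    allow_remainder: bool = False,
) -> CohortSample:
    """Exact stratified balance: equal counts from every joint stratum of
    the (all-binary) covariates.

    Requires n divisible by 2^d and every stratum to hold at least n/2^d
    rows; with ``allow_remainder`` the per-stratum quota is instead set by
    largest-remainder allocation of n over the 2^d strata.
    """
    if any(s.kind != "binary" for s in pool.specs):
        raise InvalidParameterError("joint balancing requires all-binary covariates")
    d = pool.n_covariates
    k = 2**d
    if n > pool.n_individuals:
        raise InvalidParameterError("n exceeds pool size")
    if n % k != 0 and not allow_remainder:
        raise InvalidParameterError(
            f"n={n} is not divisible by the number of joint strata 2^{d}={k}"
        )
    quotas = _stratum_quotas(n, k)
    X = pool.matrix
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for quota, levels in zip(quotas, iter_product((1, -1), repeat=d)):
        mask = np.all(X == np.asarray(levels, dtype=float), axis=1)
        rows = np.flatnonzero(mask)
        if rows.size < quota:
            raise InfeasibleStratumError(
                f"stratum {levels} holds {rows.size} individuals but {quota} are required",
                stratum=levels,
                available=int(rows.size),
                required=int(quota),
            )
        chosen.append(rng.choice(rows, size=quota, replace=False, shuffle=False))
    idx = np.concatenate(chosen)
    return CohortSample(
        indices=pool.ids[idx],
        covariates=pool.covariates.iloc[idx].reset_index(drop=True),
        specs=list(pool.specs),
        protocol="joint",
        seed=seed,
    )


def _stratum_quotas(n: int, k: int) -> list[int]:
    if n % k == 0:
        return [n // k] * k
    base, rem = divmod(n, k)
    # largest-remainder with equal targets: distribute the remainder over
    # the first `rem` strata (all remainders tie at n/k - base)
    return [base + 1 if i < rem else base for i in range(k)]


def random_sample(pool: PoolTable, n: int, seed: int = 0) -> CohortSample:
    """Simple random sample of n individuals without replacement."""
    if n > pool.n_individuals:
        raise InvalidParameterError("n exceeds pool size")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pool.n_individuals, size=n, replace=False, shuffle=False)
    return CohortSample(
        indices=pool.ids[idx],
        covariates=pool.covariates.iloc[idx].reset_index(drop=True),
        specs=list(pool.specs),
        protocol="random",
        seed=seed,
    )
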