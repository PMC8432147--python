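"""End-to-end simulation experiments.

Three studies are orchestrated here:

1. power/MSE/type-I curves over a grid of cohort sizes, comparing the
   random, marginally balanced and jointly balanced recruitment
   protocols on a fixed synthetic pool (outcomes and cohort draws are
   re-randomized each replicate);
2. sample-size finding — the smallest cohort size whose
   isotonic-regression-smoothed power reaches a target level;
3. an EHR-style prospective study: split a large pool into sub-pools,
   recruit a cohort from each by two protocols, fit Cox models and
   compare against the full-pool reference fit.

All randomness derives from a single master seed through a stable
per-(protocol, n, replicate) hash, so a run is reproducible end to end.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from . import recruitment
from .density import estimate_density, scale_to_quantile_anchors
from .exceptions import (
    InfeasibleStratumError,
    InvalidParameterError,
    NotBracketedError,
)
from .inference import (
    estimate_power,
    fit_cox,
    fit_logistic,
    minority_ratio,
    significance_overlap,
)
from .pools import (
    CoxModelSpec,
    LogisticModelSpec,
    PoolTable,
    calibrate_censoring_rate,
    generate_binary_pool,
    generate_ehr_pool,
    generate_normal_pool,
    simulate_cox_outcomes,
    simulate_logistic_outcomes,
)

__all__ = [
    "ExperimentConfig",
    "derive_seed",
    "build_pool",
    "marginal_weights",
    "run_power_curve",
    "find_n_for_power",
    "run_ehr_study",
]

logger = logging.getLogger("selrecruit")

POOL_GENERATORS = {
    "binary": generate_binary_pool,
    "normal": generate_normal_pool,
    "ehr": generate_ehr_pool,
}

CURVE_COLUMNS = [
    "protocol",
    "n",
    "power",
    "mse",
    "type1",
    "mc_se",
    "mse_se",
    "type1_se",
    "replicates",
    "status",
]


def derive_seed(master: int, protocol: str, n: int, replicate: int) -> int:
    """Deterministic per-cell seed: stable hash of (master, protocol, n,
    replicate), collision-free for practical purposes and below 2^31."""
    key = f"{master}|{protocol}|{n}|{replicate}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    """Declarative description of a power-curve experiment.

    ``pool_spec`` names a generator (``binary``/``normal``/``ehr``) with
    its keyword parameters; ``model_spec`` holds the generating logistic
    coefficients.  The pool is generated once per experiment; outcomes
    and cohort draws are re-randomized every replicate.
    """

    protocols: tuple[str, ...]
    n_grid: tuple[int, ...]
    replicates: int
    seed: int
    pool_spec: dict
    model_spec: LogisticModelSpec
    alpha: float = 0.05
    density_method: str = "kde"

    def __post_init__(self):
        self.n_grid = tuple(int(n) for n in self.n_grid)
        if list(self.n_grid) != sorted(self.n_grid):
            raise InvalidParameterError("n_grid must be ascending")
        if self.replicates < 1:
            raise InvalidParameterError("replicates must be >= 1")
        unknown = set(self.protocols) - {"random", "marginal", "joint"}
        if unknown:
            raise InvalidParameterError(f"unknown protocols: {sorted(unknown)}")


def build_pool(pool_spec: dict, seed: int) -> PoolTable:
    """Instantiate a pool from a generator name and keyword parameters."""
    spec = dict(pool_spec)
    kind = spec.pop("kind")
    if kind not in POOL_GENERATORS:
        raise InvalidParameterError(f"unknown pool generator {kind!r}")
    return POOL_GENERATORS[kind](seed=seed, **spec)


def marginal_weights(
    pool: PoolTable, density_method: str = "kde"
) -> recruitment.RecruitmentWeights:
    """Marginally balanced recruitment weights for a pool: per-covariate
    inverse-probability (binary) or density-inverse (continuous) weights
    combined by the product rule."""
    per_cov = []
    for spec in pool.specs:
        col = pool.covariates[spec.name].to_numpy()
        if spec.kind == "binary":
            per_cov.append(recruitment.binary_weights(col))
        else:
            dens = estimate_density(col, method=density_method)
            per_cov.append(recruitment.continuous_weights(dens, col))
    if len(per_cov) == 1:
        w = per_cov[0]
        return w
    return recruitment.product_weights(per_cov)


def _draw_cohort(pool, protocol, weights, n, seed):
    if protocol == "joint":
        # largest-remainder quotas let grid sizes that are not multiples of
        # the stratum count run; true stratum shortage still raises
        return recruitment.jointly_balanced_sample(pool, n, seed=seed, allow_remainder=True)
    if protocol == "random":
        return recruitment.random_sample(pool, n, seed=seed)
    return recruitment.sample_cohort(pool, weights, n, seed=seed)


def run_power_curve(config: ExperimentConfig, pool: PoolTable | None = None) -> pd.DataFrame:
    """Monte-Carlo power/MSE/type-I curve over cohort sizes and protocols.

    Returns a tidy DataFrame with one row per (protocol, n); cells where
    the joint protocol is infeasible are flagged ``status="infeasible"``
    and the run continues.  ``mc_se`` is the Monte-Carlo SE of the power
    (or of the type-I rate when the truth is entirely null).
    """
    if pool is None:
        pool = build_pool(config.pool_spec, seed=derive_seed(config.seed, "pool", 0, 0))
    model = config.model_spec
    truth = np.asarray(model.w, dtype=float)
    weights_by_protocol = {}
    for protocol in config.protocols:
        if protocol == "marginal":
            weights_by_protocol[protocol] = marginal_weights(
                pool, density_method=config.density_method
            )
        else:
            weights_by_protocol[protocol] = None

    rows = []
    for protocol in config.protocols:
        for n in config.n_grid:
            fits = []
            status = "ok"
            for rep in range(config.replicates):
                seed_r = derive_seed(config.seed, protocol, n, rep)
                try:
                    cohort = _draw_cohort(
                        pool, protocol, weights_by_protocol[protocol], n, seed_r
                    )
                except InfeasibleStratumError as exc:
                    logger.info("protocol=%s n=%d infeasible: %s", protocol, n, exc)
                    status = "infeasible"
                    break
                y = simulate_logistic_outcomes(cohort.matrix, model, seed=seed_r)
                fits.append(fit_logistic(cohort.matrix, y))
            if status == "infeasible":
                rows.append(
                    dict(
                        protocol=protocol, n=n, power=np.nan, mse=np.nan,
                        type1=np.nan, mc_se=np.nan, mse_se=np.nan,
                        type1_se=np.nan, replicates=0, status=status,
                    )
                )
                continue
            summary = estimate_power(fits, truth, alpha=config.alpha)
            rows.append(
                dict(
                    protocol=protocol,
                    n=n,
                    power=np.nan if summary.power is None else summary.power,
                    mse=summary.mse,
                    type1=np.nan if summary.type1 is None else summary.type1,
                    mc_se=summary.mc_se.get("power", summary.mc_se.get("type1", np.nan)),
                    mse_se=summary.mc_se.get("mse", np.nan),
                    type1_se=summary.mc_se.get("type1", np.nan),
                    replicates=summary.n_replicates,
                    status=status,
                )
            )
            logger.info(
                "protocol=%s n=%d power=%s mse=%.5f (%d replicates)",
                protocol, n, rows[-1]["power"], summary.mse, summary.n_replicates,
            )
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def find_n_for_power(curve: pd.DataFrame, target: float) -> dict[str, dict]:
    """Smallest cohort size reaching a target power, per protocol.

    The Monte-Carlo power curve is smoothed by isotonic regression
    (power is non-decreasing in n up to noise); the result reports the
    smallest grid n whose smoothed power reaches the target and the
    linear interpolation between the bracketing grid points.
    """
    out: dict[str, dict] = {}
    for protocol, grp in curve[curve["status"] == "ok"].groupby("protocol", sort=False):
        grp = grp.sort_values("n")
        n = grp["n"].to_numpy(dtype=float)
        power = grp["power"].to_numpy(dtype=float)
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        smoothed = iso.fit_transform(n, power)
        above = smoothed >= target
        if not above.any():
            raise NotBracketedError(
                f"protocol {protocol!r}: max smoothed power "
                f"{smoothed.max():.3f} never reaches target {target}"
            )
        if smoothed[0] >= target:
            raise NotBracketedError(
                f"protocol {protocol!r}: smoothed power already exceeds the "
                f"target at the smallest grid n={int(n[0])}"
            )
        first = int(np.argmax(above))
        n_lo, n_hi = n[first - 1], n[first]
        p_lo, p_hi = smoothed[first - 1], smoothed[first]
        if p_hi > p_lo:
            n_interp = n_lo + (target - p_lo) / (p_hi - p_lo) * (n_hi - n_lo)
        else:
            n_interp = n_hi
        out[protocol] = {
            "n_grid": int(n[first]),
            "n_interpolated": float(n_interp),
            "target": float(target),
        }
    for protocol in curve["protocol"].unique():
        if protocol not in out:
            raise NotBracketedError(f"protocol {protocol!r}: no feasible grid cells")
    return out


# ---------------------------------------------------------------------------
# EHR-style split-pool Cox study
# ---------------------------------------------------------------------------


@dataclass
class EHRStudyReport:
    """Results of the split-pool Cox study (see :func:`run_ehr_study`)."""

    truth: np.ndarray
    null_indices: np.ndarray
    censor_rate: float
    reference_n_significant: int
    n_subpools: int
    cohort_n: int
    per_protocol: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "truth": self.truth.tolist(),
            "null_indices": self.null_indices.tolist(),
            "censor_rate": self.censor_rate,
            "reference_n_significant": self.reference_n_significant,
            "n_subpools": self.n_subpools,
            "cohort_n": self.cohort_n,
            "protocols": self.per_protocol,
        }


def run_ehr_study(
    pool: PoolTable | None = None,
    *,
    n_subpools: int = 10,
    cohort_n: int = 1000,
    protocols: tuple[str, ...] = ("marginal", "random"),
    alpha: float = 0.05,
    seed: int = 0,
    pool_size: int = 82089,
    n_null: int = 3,
    effect_range: tuple[float, float] = (0.05, 0.25),
    baseline_rate: float = 0.05,
    target_event_fraction: float = 0.23,
    density_method: str = "kde",
) -> EHRStudyReport:
    """Simulated prospective time-to-event study on an EHR-style pool.

    The pool (generated if not supplied) has its continuous covariates
    rescaled so the 0.05/0.95 quantiles sit at -1/+1.  A generating Cox
    coefficient vector is drawn once (seeded): ``n_null`` randomly chosen
    coefficients are exactly zero and the rest have magnitudes uniform in
    ``effect_range`` with random signs.  Exponential censoring is
    calibrated so the expected event fraction matches
    ``target_event_fraction``.  Outcomes are simulated once for the whole
    pool (as in a registry, they pre-exist recruitment); a reference Cox
    model is fitted to the full pool; the pool is then shuffled and split
    into ``n_subpools`` equal sub-pools and from each a cohort of
    ``cohort_n`` is recruited under every protocol and refitted.

    Reported per protocol (averaged over sub-pools): significant-
    coefficient overlap with the reference fit, mean squared coefficient
    difference to the reference, median minority ratio, and the number of
    truly nonzero coefficients recovered.
    """
    if pool is None:
        pool = generate_ehr_pool(N=pool_size, seed=derive_seed(seed, "ehr-pool", 0, 0))
    # quantile-anchor scaling of continuous covariates (pool-level convention)
    scaled = pool.covariates.copy()
    for spec in pool.specs:
        if spec.kind == "continuous":
            scaled[spec.name] = scale_to_quantile_anchors(scaled[spec.name].to_numpy())
    # ids are reset to row positions so outcome vectors index directly
    pool = PoolTable(scaled, list(pool.specs), ids=np.arange(len(scaled)))

    d = pool.n_covariates
    rng = np.random.default_rng(derive_seed(seed, "ehr-beta", 0, 0))
    beta = rng.uniform(effect_range[0], effect_range[1], size=d) * rng.choice(
        (-1.0, 1.0), size=d
    )
    null_idx = rng.choice(d, size=n_null, replace=False)
    beta[null_idx] = 0.0

    censor_rate = calibrate_censoring_rate(
        pool, beta, baseline_rate, target_event_fraction
    )
    model = CoxModelSpec(beta=tuple(beta), baseline_rate=baseline_rate,
                         censor_rate=censor_rate)
    times, events = simulate_cox_outcomes(
        pool, model, seed=derive_seed(seed, "ehr-outcomes", 0, 0)
    )
    names = [s.name for s in pool.specs]
    logger.info("EHR study: fitting reference Cox model on N=%d", pool.n_individuals)
    reference_fit = fit_cox(pool.matrix, times, events, names=names)

    N = pool.n_individuals
    sub_size = N // n_subpools
    if sub_size < cohort_n:
        raise InvalidParameterError("sub-pools smaller than the requested cohort")
    dropped = N - sub_size * n_subpools
    if dropped:
        logger.info("EHR study: dropping %d remainder rows after split", dropped)
    order = np.random.default_rng(derive_seed(seed, "ehr-split", 0, 0)).permutation(N)

    nonzero_mask = beta != 0
    per_protocol: dict[str, dict] = {}
    for protocol in protocols:
        rows = []
        for k in range(n_subpools):
            sub_idx = order[k * sub_size : (k + 1) * sub_size]
            subpool = pool.subset(sub_idx)
            seed_k = derive_seed(seed, f"ehr-{protocol}", cohort_n, k)
            if protocol == "random":
                cohort = recruitment.random_sample(subpool, cohort_n, seed=seed_k)
            else:
                w = marginal_weights(subpool, density_method=density_method)
                cohort = recruitment.sample_cohort(subpool, w, cohort_n, seed=seed_k)
            # cohort.indices are row positions in the (rebuilt) pool
            rows_in_pool = cohort.indices
            cohort_fit = fit_cox(
                cohort.matrix, times[rows_in_pool], events[rows_in_pool], names=names
            )
            overlap = significance_overlap(cohort_fit, reference_fit, alpha=alpha)
            ratios = minority_ratio(cohort)
            recovered = int(
                np.count_nonzero(
                    (cohort_fit.slope_p_values < alpha) & nonzero_mask
                )
            )
            rows.append(
                dict(
                    subpool=k,
                    n_both_significant=overlap.n_both_significant,
                    n_cohort_only=overlap.n_cohort_only,
                    msd_to_reference=overlap.msd,
                    median_minority_ratio=ratios.median,
                    n_true_nonzero_recovered=recovered,
                )
            )
            logger.info(
                "EHR study: protocol=%s subpool=%d overlap=%d msd=%.4f",
                protocol, k, overlap.n_both_significant, overlap.msd,
            )
        df = pd.DataFrame(rows)
        per_protocol[protocol] = {
            "mean_significant_overlap": float(df["n_both_significant"].mean()),
            "mean_cohort_only_significant": float(df["n_cohort_only"].mean()),
            "mean_msd_to_reference": float(df["msd_to_reference"].mean()),
            "median_minority_ratio": float(df["median_minority_ratio"].median()),
            "mean_true_nonzero_recovered": float(df["n_true_nonzero_recovered"].mean()),
            "per_subpool": rows,
        }

    return EHRStudyReport(
        truth=beta,
        null_indices=np.sort(null_idx),
        censor_rate=censor_rate,
        reference_n_significant=int(
            np.count_nonzero(reference_fit.slope_p_values < alpha)
        ),
        n_subpools=n_subpools,
        cohort_n=cohort_n,
        per_protocol=per_protocol,
    )
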