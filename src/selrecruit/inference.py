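"""Model fitting and Monte-Carlo evaluation metrics.

Cohorts are evaluated by fitting the generating model class (logistic
regression for binary outcomes, Cox proportional hazards for
time-to-event outcomes) and summarizing across replicates:

* power — proportion of truly nonzero coefficients whose two-sided Wald
  test rejects at level alpha;
* type-I error — the same proportion over truly zero coefficients;
* mean square error — mean squared deviation of the non-intercept
  estimates from the generating coefficients.

Significance is per-coefficient Wald with no multiple-testing
correction, matching common simulation practice at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateOutcomeError, InvalidParameterError

__all__ = [
    "FitResult",
    "MetricSummary",
    "MinorityRatios",
    "OverlapSummary",
    "fit_logistic",
    "fit_cox",
    "estimate_power",
    "minority_ratio",
    "significance_overlap",
]


@dataclass
class FitResult:
    """Coefficients and Wald p-values from one fitted model.

    ``estimates`` includes the intercept first for logistic fits
    (``has_intercept=True``) and only log-hazard ratios for Cox fits.
    """

    estimates: np.ndarray
    p_values: np.ndarray
    converged: bool
    has_intercept: bool
    names: list[str] = field(default_factory=list)
    standard_errors: np.ndarray | None = None

    @property
    def slopes(self) -> np.ndarray:
        return self.estimates[1:] if self.has_intercept else self.estimates

    @property
    def slope_p_values(self) -> np.ndarray:
        return self.p_values[1:] if self.has_intercept else self.p_values


@dataclass
class MetricSummary:
    """Power / MSE / type-I estimates with Monte-Carlo standard errors."""

    power: float | None
    mse: float
    type1: float | None
    mc_se: dict
    n_replicates: int
    alpha: float
    per_coefficient_power: np.ndarray | None = None


def fit_logistic(X, y) -> FitResult:
    """Maximum-likelihood logistic regression of y in {-1,+1} on X.

    Non-convergence and perfect separation are reported through the
    ``converged`` flag rather than raised; a single-class outcome is a
    hard error.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    y01 = (y == 1).astype(float)
    if y01.min() == y01.max():
        raise DegenerateOutcomeError("outcome vector contains a single class")
    design = sm.add_constant(X, has_constant="add")
    names = ["intercept"] + [f"x{i+1}" for i in range(X.shape[1])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y01, design).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            params = np.asarray(res.params, dtype=float)
            pvals = np.asarray(res.pvalues, dtype=float)
            bse = np.asarray(res.bse, dtype=float)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            k = design.shape[1]
            return FitResult(
                estimates=np.full(k, np.nan),
                p_values=np.full(k, np.nan),
                converged=False,
                has_intercept=True,
                names=names,
            )
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(pvals)):
        converged = False
    return FitResult(
        estimates=params,
        p_values=pvals,
        converged=converged,
        has_intercept=True,
        names=names,
        standard_errors=bse,
    )


def fit_cox(X, times, events, names: list[str] | None = None) -> FitResult:
    """Cox proportional-hazards partial-likelihood fit with Wald p-values.

    Ties are handled by Efron's approximation (the lifelines default).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    events = np.asarray(events)
    if events.sum() < 1:
        raise DegenerateOutcomeError("no events observed; Cox fit undefined")
    if names is None:
        names = [f"x{i+1}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    df["time"] = np.asarray(times, dtype=float)
    df["event"] = events.astype(int)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, np.linalg.LinAlgError):
            return FitResult(
                estimates=np.full(X.shape[1], np.nan),
                p_values=np.full(X.shape[1], np.nan),
                converged=False,
                has_intercept=False,
                names=names,
            )
    params = cph.params_.reindex(names).to_numpy(dtype=float)
    pvals = cph.summary["p"].reindex(names).to_numpy(dtype=float)
    bse = cph.summary["se(coef)"].reindex(names).to_numpy(dtype=float)
    return FitResult(
        estimates=params,
        p_values=pvals,
        converged=True,
        has_intercept=False,
        names=names,
        standard_errors=bse,
    )


def estimate_power(
    fits: list[FitResult],
    truth,
    alpha: float = 0.05,
) -> MetricSummary:
    """Aggregate power, type-I error and MSE over Monte-Carlo replicates.

    ``truth`` is the generating non-intercept coefficient vector.  Power
    pools the rejection indicators over all coefficients with nonzero
    truth ("proportion of inferred parameters significant"); type-I does
    the same over zero-truth coefficients.  Non-converged fits are
    excluded.  Monte-Carlo SEs use the binomial formula for proportions
    and the empirical standard error for the MSE.
    """
    if not fits:
        raise InvalidParameterError("need at least one fit")
    truth = np.asarray(truth, dtype=float)
    used = [f for f in fits if f.converged and np.all(np.isfinite(f.slopes))]
    if not used:
        raise InvalidParameterError("no converged fits to summarize")
    slopes = np.vstack([f.slopes for f in used])
    pvals = np.vstack([f.slope_p_values for f in used])
    if slopes.shape[1] != truth.size:
        raise InvalidParameterError("truth dimension does not match fitted slopes")

    nonzero = truth != 0
    reject = pvals < alpha
    R = len(used)
    mc_se: dict[str, float] = {}

    if nonzero.any():
        per_rep_power = reject[:, nonzero].mean(axis=1)
        power = float(per_rep_power.mean())
        mc_se["power"] = float(np.sqrt(power * (1 - power) / R))
        per_coef_power = reject[:, nonzero].mean(axis=0)
    else:
        power, per_coef_power = None, None
    if (~nonzero).any():
        per_rep_t1 = reject[:, ~nonzero].mean(axis=1)
        type1 = float(per_rep_t1.mean())
        mc_se["type1"] = float(np.sqrt(type1 * (1 - type1) / R))
    else:
        type1 = None

    per_rep_mse = ((slopes - truth) ** 2).mean(axis=1)
    mse = float(per_rep_mse.mean())
    mc_se["mse"] = float(per_rep_mse.std(ddof=1) / np.sqrt(R)) if R > 1 else 0.0

    return MetricSummary(
        power=power,
        mse=mse,
        type1=type1,
        mc_se=mc_se,
        n_replicates=R,
        alpha=alpha,
        per_coefficient_power=per_coef_power,
    )


@dataclass
class MinorityRatios:
    """Cohort balance diagnostic for binary covariates.

    For each binary covariate, the count of the less frequent level
    divided by the count of the more frequent level (1 = perfect
    balance, 0 = one level absent), with the median across covariates.
    """

    per_covariate: pd.Series
    median: float


def minority_ratio(cohort) -> MinorityRatios:
    """Minority-to-majority count ratio per binary covariate of a cohort."""
    binary_names = [s.name for s in cohort.specs if s.kind == "binary"]
    if not binary_names:
        raise InvalidParameterError("cohort has no binary covariates")
    ratios = {}
    for name in binary_names:
        col = cohort.covariates[name].to_numpy()
        n_plus = int(np.count_nonzero(col == 1))
        n_minus = col.size - n_plus
        lo, hi = min(n_plus, n_minus), max(n_plus, n_minus)
        ratios[name] = lo / hi if hi > 0 else 0.0
    series = pd.Series(ratios)
    return MinorityRatios(per_covariate=series, median=float(series.median()))


@dataclass
class OverlapSummary:
    """Agreement between a cohort fit and a reference (full-pool) fit."""

    n_both_significant: int
    n_cohort_only: int
    n_reference_significant: int
    msd: float  # mean squared difference of non-intercept coefficients


def significance_overlap(
    cohort_fit: FitResult,
    reference_fit: FitResult,
    alpha: float = 0.05,
) -> OverlapSummary:
    """Count shared/extra significant coefficients and the mean squared
    coefficient difference between a cohort fit and a reference fit."""
    if cohort_fit.slopes.size != reference_fit.slopes.size:
        raise InvalidParameterError("fits have different numbers of coefficients")
    sig_c = cohort_fit.slope_p_values < alpha
    sig_r = reference_fit.slope_p_values < alpha
    msd = float(np.mean((cohort_fit.slopes - reference_fit.slopes) ** 2))
    return OverlapSummary(
        n_both_significant=int(np.count_nonzero(sig_c & sig_r)),
        n_cohort_only=int(np.count_nonzero(sig_c & ~sig_r)),
        n_reference_significant=int(np.count_nonzero(sig_r)),
        msd=msd,
    )
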