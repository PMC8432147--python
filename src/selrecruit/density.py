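"""Empirical density and quantile machinery for continuous covariates.

The continuous recruitment rule inverts the pool density between its
0.05 and 0.95 quantiles, so it needs three ingredients: an empirical
density estimate p_hat(x), the quantiles x_l < x_u, and the derived
constants q = 1/(x_u - x_l) (the height of the uniform target) and
c' = max_{x_l <= x <= x_u} q / p_hat(x) (which caps the unnormalized
weight at 1).  This module also provides the convention of linearly
rescaling a continuous column so its 0.05/0.95 quantiles sit at -1/+1,
and the +1-proportion summary used by the binary rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .exceptions import CodingError, DegenerateDensityError, DegenerateScaleError

__all__ = [
    "DensityEstimate",
    "BinaryCovariateSummary",
    "estimate_density",
    "binary_summary",
    "scale_to_quantile_anchors",
]

#: Floor applied to density values before division, so that weights stay
#: finite in regions the estimator assigns (numerically) zero mass.
DENSITY_FLOOR = 1e-12

_GRID_POINTS = 512


@dataclass
class DensityEstimate:
    """Empirical density of a pool covariate with its quantile constants.

    Attributes
    ----------
    evaluate
        Vectorized callable returning p_hat(x) >= DENSITY_FLOOR.
    x_l, x_u
        Lower/upper pool quantiles (default levels 0.05/0.95).
    q
        Height of the uniform target on [x_l, x_u]: 1/(x_u - x_l).
    c_prime
        max over [x_l, x_u] of q / p_hat(x), evaluated on a dense grid;
        dividing by it keeps every in-interval weight at or below 1.
    """

    evaluate: Callable[[np.ndarray], np.ndarray]
    x_l: float
    x_u: float
    q: float
    c_prime: float


def estimate_density(
    values,
    lower_q: float = 0.05,
    upper_q: float = 0.95,
    method: str = "kde",
    bins: int = 50,
) -> DensityEstimate:
    """Estimate the pool density of a continuous covariate.

    By default a Gaussian kernel density estimate with Silverman's
    bandwidth; ``method="histogram"`` switches to a density-normalized
    histogram with ``bins`` equal-width bins (step-function evaluation).
    Quantiles use the linear-interpolation empirical definition.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not lower_q < upper_q:
        raise ValueError("lower_q must be below upper_q")
    if np.unique(x).size < 10:
        raise DegenerateDensityError(
            "need at least 10 distinct values to estimate a density"
        )
    x_l, x_u = np.quantile(x, [lower_q, upper_q])
    if not x_l < x_u:
        raise DegenerateDensityError("quantiles coincide; density is degenerate")

    if method == "kde":
        kde = stats.gaussian_kde(x, bw_method="silverman")

        def evaluate(pts):
            return np.maximum(kde(np.atleast_1d(np.asarray(pts, dtype=float))), DENSITY_FLOOR)

    elif method == "histogram":
        heights, edges = np.histogram(x, bins=bins, density=True)

        def evaluate(pts):
            pts = np.atleast_1d(np.asarray(pts, dtype=float))
            idx = np.clip(np.searchsorted(edges, pts, side="right") - 1, 0, len(heights) - 1)
            out = heights[idx].astype(float)
            out[(pts < edges[0]) | (pts > edges[-1])] = 0.0
            return np.maximum(out, DENSITY_FLOOR)

    else:
        raise ValueError(f"unknown density method {method!r}")

    q = 1.0 / (x_u - x_l)
    grid = np.linspace(x_l, x_u, _GRID_POINTS)
    c_prime = float(np.max(q / evaluate(grid)))
    return DensityEstimate(evaluate=evaluate, x_l=float(x_l), x_u=float(x_u), q=q, c_prime=c_prime)


@dataclass(frozen=True)
class BinaryCovariateSummary:
    """Proportion of the pool coded +1 for one binary covariate."""

    p_plus: float

    def __post_init__(self):
        if not 0.0 <= self.p_plus <= 1.0:
            raise ValueError("p_plus must lie in [0, 1]")


def binary_summary(values) -> BinaryCovariateSummary:
    """Summarize a -1/+1 coded column by its +1 proportion (exact count ratio)."""
    x = np.asarray(values)
    if not np.all(np.isin(x, (-1, 1))):
        raise CodingError("binary column must be coded -1/+1")
    return BinaryCovariateSummary(p_plus=float(np.count_nonzero(x == 1) / x.size))


def scale_to_quantile_anchors(
    values,
    lower_q: float = 0.05,
    upper_q: float = 0.95,
) -> np.ndarray:
    """Linearly rescale a continuous column so its lower/upper quantiles map
    to -1 and +1.

    The affine map is order-preserving (positive slope); values outside the
    quantile span map beyond +-1.
    """
    x = np.asarray(values, dtype=float)
    q05, q95 = np.quantile(x, [lower_q, upper_q])
    if not q05 < q95:
        raise DegenerateScaleError("quantile anchors coincide; cannot rescale")
    return (2.0 * x - (q95 + q05)) / (q95 - q05)
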