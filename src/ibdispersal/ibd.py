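"""Isolation-by-distance regressions with locus-resampling intervals.

A pairwise genetic metric is regressed on the natural log of geographic
distance over a distance window:

    metric = a + b * ln(d)

Pairs share individuals, so naive pair-level OLS standard errors are
invalid; all uncertainty comes from resampling loci — percentile bootstrap
over loci (recomputing pair values from resampled per-locus contributions
by ratio of sums) or a delete-one-locus jackknife.  A slope is called
significant when its 95% CI excludes zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .metrics import PairMetricTable

logger = logging.getLogger(__name__)


@dataclass
class IbDFit:
    """OLS fit of a genetic metric against ln(distance)."""

    metric_name: str
    slope: float
    intercept: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    ci_method: str | None = None
    window: tuple[float, float] = (0.0, float("inf"))
    n_pairs: int = 0
    slope_draws: np.ndarray | None = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        return (
            np.isfinite(self.ci_low)
            and np.isfinite(self.ci_high)
            and self.ci_low * self.ci_high > 0
        )

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "slope": self.slope,
            "intercept": self.intercept,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
            "window_m": list(self.window),
            "n_pairs": self.n_pairs,
            "significant": bool(self.significant),
        }


def _window_mask(t: PairMetricTable, window) -> np.ndarray:
    d_min, d_max = window
    if not d_min < d_max:
        raise ValueError("window must satisfy d_min < d_max")
    return (t.d >= d_min) & (t.d <= d_max) & np.isfinite(t.d)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xc = x - x.mean()
    ss = (xc ** 2).sum()
    if ss == 0:
        raise ValueError("zero variance in ln(d): cannot fit IbD slope")
    b = float((xc * y).sum() / ss)
    a = float(y.mean() - b * x.mean())
    return b, a


def fit_ibd(t: PairMetricTable, window=(0.0, float("inf"))) -> IbDFit:
    """Point-estimate OLS of the metric on ln(d) within the window."""
    mask = _window_mask(t, window)
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} pair(s) inside window {window}; need >= 3"
        )
    sub = t.subset(mask)
    b, a = _ols(np.log(sub.d), sub.values())
    return IbDFit(t.metric_name, b, a, window=tuple(window), n_pairs=sub.n_pairs)


def bootstrap_ci_loci(
    t: PairMetricTable,
    window=(0.0, float("inf")),
    n_boot: int = 1000,
    seed: int = 0,
) -> IbDFit:
    """Percentile bootstrap over loci for the IbD slope.

    Loci are resampled with replacement; pair values are recomputed from
    resampled per-locus numerators/denominators (ratio of sums) and the
    regression refit.  Deterministic for a fixed seed.  Degenerate
    resamples (zero denominator for any pair) are discarded and logged.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot = {n_boot} is small; CI will be noisy")
    fit = fit_ibd(t, window)
    sub = t.subset(_window_mask(t, window))
    L = sub.n_loci
    rng = np.random.default_rng(seed)
    # multinomial locus weights, all resamples at once
    w = rng.multinomial(L, np.full(L, 1.0 / L), size=n_boot).T.astype(np.float64)
    num_b = sub.num @ w  # (n_pairs, n_boot)
    den_b = sub.den @ w
    good = (den_b > 0).all(axis=0)
    n_bad = int((~good).sum())
    if n_bad:
        logger.info("bootstrap: discarded %d degenerate resample(s)", n_bad)
    y = num_b[:, good] / den_b[:, good]
    x = np.log(sub.d)
    xc = x - x.mean()
    ss = (xc ** 2).sum()
    slopes = (xc @ y) / ss
    lo, hi = np.percentile(slopes, [2.5, 97.5])
    fit.ci_low, fit.ci_high = float(lo), float(hi)
    fit.ci_method = "bootstrap_loci"
    fit.slope_draws = slopes
    return fit


def jackknife_ci_loci(t: PairMetricTable, window=(0.0, float("inf"))) -> IbDFit:
    """Delete-one-locus jackknife CI for the IbD slope.

    SE = sqrt(((L-1)/L) * sum_l (b_(-l) - b_mean)^2); CI = b +/- 1.96 SE.
    """
    fit = fit_ibd(t, window)
    sub = t.subset(_window_mask(t, window))
    L = sub.n_loci
    if L < 2:
        raise ValueError("jackknife needs at least 2 loci")
    num_tot = sub.num.sum(axis=1, keepdims=True)
    den_tot = sub.den.sum(axis=1, keepdims=True)
    num_loo = num_tot - sub.num  # (n_pairs, L)
    den_loo = den_tot - sub.den
    with np.errstate(invalid="ignore", divide="ignore"):
        y = num_loo / den_loo
    x = np.log(sub.d)
    xc = x - x.mean()
    ss = (xc ** 2).sum()
    ok = np.isfinite(y).all(axis=0)
    slopes = (xc @ y[:, ok]) / ss
    bbar = slopes.mean()
    Leff = slopes.size
    se = float(np.sqrt((Leff - 1) / Leff * ((slopes - bbar) ** 2).sum()))
    fit.ci_low = fit.slope - 1.96 * se
    fit.ci_high = fit.slope + 1.96 * se
    fit.ci_method = "jackknife_loci"
    return fit
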