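"""Neighbourhood size, density and generational dispersal distance.

Wright's genetic neighbourhood for a 2D continuously distributed
population is NS = 4*pi*D*sigma^2 — the effective number of individuals in
a circle of radius 2*sigma, where sigma^2 is the mean squared axial
parent-offspring displacement and D the density of individuals per m^2.

NS is extracted from an IbD slope b:

* Rousset's a-hat (genetic distance, b > 0 under IbD):  NS = 1 / b
* Loiselle's F (kinship, b < 0 under IbD):  NS = (1 - F(1)) / (-b),
  where F(1) is the mean kinship among neighbouring pairs.  (The literal
  alternative reading NS = 1 / (-b (1 - F(1))) is available via a flag.)

Given NS and an independent density D, sigma = sqrt(NS / (4*pi*D)); under a
Gaussian dispersal kernel sigma is 1.25x the mean Euclidean parent-
offspring distance.  Uncertainty in NS and D is propagated by Monte-Carlo:
each parameter given as (central, 95% CI) is resampled from a two-piece
lognormal matched at the median and both CI endpoints (positive support,
asymmetric intervals), NS preferentially from locus-bootstrap slope draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .ibd import IbDFit, bootstrap_ci_loci, fit_ibd
from .metrics import PairMetricTable, mean_kinship_first_class

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054
FOUR_PI = 4.0 * math.pi
#: sigma = GAUSSIAN_SIGMA_FACTOR * mean Euclidean dispersal distance
GAUSSIAN_SIGMA_FACTOR = 1.25


@dataclass
class DensityEstimate:
    """Individuals (genets) per m^2, census or effective."""

    kind: str  # "census" | "effective"
    central: float
    ci_low: float
    ci_high: float
    area_m2: float | None = None
    plot_densities: list[float] | None = None

    def __post_init__(self) -> None:
        if self.central <= 0:
            raise ValueError("density must be positive")
        if not self.ci_low <= self.central <= self.ci_high:
            raise ValueError("CI must bracket the central density")


@dataclass
class SigmaEstimate:
    """Monte-Carlo distribution of generational dispersal distance."""

    median: float
    pi_90: tuple[float, float]
    n_draws: int
    n_nonfinite: int
    seed: int
    density_kind: str
    metric: str
    draws: np.ndarray = field(repr=False, default=None)
    flag: str | None = None

    def to_dict(self) -> dict:
        return {
            "median_m": self.median,
            "pi_90_m": list(self.pi_90),
            "n_draws": self.n_draws,
            "n_nonfinite": self.n_nonfinite,
            "seed": self.seed,
            "density_kind": self.density_kind,
            "metric": self.metric,
            "flag": self.flag,
        }


class TwoPieceLogNormal:
    """Split lognormal matched to a median and 95% CI endpoints.

    Draws are exp(mu + s_lo * Z) for Z < 0 and exp(mu + s_hi * Z) for
    Z >= 0 with Z standard normal, so the median is exp(mu) exactly and the
    2.5%/97.5% quantiles hit the CI endpoints.
    """

    def __init__(self, central: float, ci_low: float, ci_high: float, level: float = 0.95):
        if not 0 < ci_low <= central <= ci_high:
            raise ValueError("need 0 < ci_low <= central <= ci_high")
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        self.mu = math.log(central)
        self.s_lo = math.log(central / ci_low) / z
        self.s_hi = math.log(ci_high / central) / z

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(n)
        return np.exp(self.mu + np.where(z < 0, self.s_lo, self.s_hi) * z)


# ---------------------------------------------------------------------------
# Neighbourhood size from slopes
# ---------------------------------------------------------------------------

def ns_from_rousset(b: float | np.ndarray):
    """NS = 1/b; a non-positive slope is inconsistent with IbD -> +inf."""
    b = np.asarray(b, dtype=float)
    with np.errstate(divide="ignore"):
        ns = np.where(b > 0, 1.0 / np.where(b > 0, b, 1.0), np.inf)
    return float(ns) if ns.ndim == 0 else ns


def ns_from_loiselle(b: float | np.ndarray, f1: float, literal_printed: bool = False):
    """NS from a kinship IbD slope (b < 0 under IbD) and neighbour kinship F(1).

    Standard Sp-statistic form NS = (1 - F(1)) / (-b); ``literal_printed``
    switches to the alternative reading NS = 1 / (-b (1 - F(1))).
    """
    if not 0 <= f1 < 1:
        raise ValueError("F(1) must be in [0, 1)")
    b = np.asarray(b, dtype=float)
    safe = np.where(b < 0, -b, 1.0)
    if literal_printed:
        ns = np.where(b < 0, 1.0 / (safe * (1.0 - f1)), np.inf)
    else:
        ns = np.where(b < 0, (1.0 - f1) / safe, np.inf)
    return float(ns) if ns.ndim == 0 else ns


def ns_from_fit(fit: IbDFit, f1: float | None = None, literal_printed: bool = False) -> float:
    if fit.metric_name == "rousset_a":
        return ns_from_rousset(fit.slope)
    if fit.metric_name == "loiselle_F":
        if f1 is None:
            raise ValueError("Loiselle NS needs F(1)")
        return ns_from_loiselle(fit.slope, f1, literal_printed)
    raise ValueError(f"unknown metric {fit.metric_name!r}")


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def census_density(
    genets_per_plot: dict[str, int], plot_areas: dict[str, float]
) -> DensityEstimate:
    """Census density of multilocus genotypes from per-plot genet counts.

    Central = pooled genets / pooled area; the CI is the min-max range of
    per-plot densities (each plot is one census estimate of D_c).
    """
    plots = sorted(genets_per_plot)
    if any(plot_areas.get(p, 0) <= 0 for p in plots):
        raise ValueError("every plot needs a positive area")
    dens = [genets_per_plot[p] / plot_areas[p] for p in plots]
    total = sum(genets_per_plot[p] for p in plots)
    area = sum(plot_areas[p] for p in plots)
    central = total / area
    lo, hi = (min(dens), max(dens)) if len(dens) > 1 else (central, central)
    lo, hi = min(lo, central), max(hi, central)
    return DensityEstimate("census", central, lo, hi, area_m2=area, plot_densities=dens)


def effective_density(
    ne_central: float, ne_ci: tuple[float, float], area_m2: float
) -> DensityEstimate:
    """Effective density D_e = N_e / area, CI scaled identically.

    N_e comes from an external contemporary estimator (e.g. the sibship
    method); this package does not infer it.
    """
    if ne_central <= 0:
        raise ValueError("N_e must be positive")
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    return DensityEstimate(
        "effective",
        ne_central / area_m2,
        ne_ci[0] / area_m2,
        ne_ci[1] / area_m2,
        area_m2=area_m2,
    )


# ---------------------------------------------------------------------------
# Sigma
# ---------------------------------------------------------------------------

def sigma_point(ns: float, density: float) -> float:
    """sigma = sqrt(NS / (4 pi D)); a sentinel NS propagates to sigma."""
    if not np.isfinite(ns) or ns <= 0:
        return float("inf")
    if density <= 0:
        raise ValueError("density must be positive")
    return math.sqrt(ns / (FOUR_PI * density))


def mean_dispersal_distance(sigma: float) -> float:
    """Mean Euclidean parent-offspring distance under a Gaussian kernel."""
    return sigma / GAUSSIAN_SIGMA_FACTOR


@dataclass
class NSSource:
    """Neighbourhood-size input for Monte-Carlo sigma: slope draws or CI."""

    metric: str
    slopes: np.ndarray | None = None
    f1: float | None = None
    central: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    literal_printed: bool = False

    @classmethod
    def from_slopes(cls, fit: IbDFit, f1: float | None = None, literal_printed=False):
        if fit.slope_draws is None:
            raise ValueError("fit carries no bootstrap slope draws")
        return cls(fit.metric_name, slopes=np.asarray(fit.slope_draws), f1=f1,
                   literal_printed=literal_printed)

    @classmethod
    def from_ci(cls, metric: str, central: float, ci_low: float, ci_high: float):
        return cls(metric, central=central, ci_low=ci_low, ci_high=ci_high)

    def draw_ns(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.slopes is not None:
            b = rng.choice(self.slopes, size=n, replace=True)
            if self.metric == "rousset_a":
                return ns_from_rousset(b)
            return ns_from_loiselle(b, self.f1, self.literal_printed)
        return TwoPieceLogNormal(self.central, self.ci_low, self.ci_high).sample(n, rng)


def sigma_distribution(
    ns_source: NSSource,
    density: DensityEstimate,
    n_draws: int = 2000,
    seed: int = 0,
    resample_plot_densities: bool = False,
) -> SigmaEstimate:
    """Monte-Carlo distribution of sigma from independent NS and D draws.

    Per draw sigma = sqrt(NS / (4 pi D)).  Draws with a sentinel NS
    (slope inconsistent with IbD) are truncated at zero and counted as
    non-finite; the median and the 5th-95th percentile interval summarise
    the finite draws.  More than 50% non-finite flags the slope as
    indistinguishable from zero.
    """
    rng = np.random.default_rng(seed)
    ns = ns_source.draw_ns(n_draws, rng)
    if resample_plot_densities and density.plot_densities:
        d = rng.choice(np.asarray(density.plot_densities, dtype=float), size=n_draws)
    elif density.ci_low == density.ci_high == density.central:
        d = np.full(n_draws, density.central)
    else:
        d = TwoPieceLogNormal(density.central, density.ci_low, density.ci_high).sample(
            n_draws, rng
        )
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        sig = np.sqrt(ns / (FOUR_PI * d))
    finite = np.isfinite(sig) & (sig > 0)
    n_nonfinite = int(n_draws - finite.sum())
    flag = None
    if n_nonfinite > 0.5 * n_draws:
        flag = "slope indistinguishable from 0"
        logger.warning("sigma distribution: %s (%d/%d draws non-finite)",
                       flag, n_nonfinite, n_draws)
    draws = sig[finite]
    if draws.size == 0:
        return SigmaEstimate(float("nan"), (float("nan"), float("nan")), n_draws,
                             n_nonfinite, seed, density.kind, ns_source.metric,
                             draws=draws, flag=flag or "no finite draws")
    lo, med, hi = np.percentile(draws, [5, 50, 95])
    return SigmaEstimate(float(med), (float(lo), float(hi)), n_draws, n_nonfinite,
                         seed, density.kind, ns_source.metric, draws=draws, flag=flag)


# ---------------------------------------------------------------------------
# Iterative spatial-scale adjustment
# ---------------------------------------------------------------------------

@dataclass
class IterationResult:
    fit: IbDFit
    sigma: float
    f1: float | None
    history: list[dict]
    flag: str  # "converged" | "scale-unresolved" | "max-iterations"


def iterate_sigma(
    t: PairMetricTable,
    density: DensityEstimate,
    k_max: float = 20.0,
    tol: float = 0.05,
    max_iter: int = 20,
    density_fn=None,
    literal_printed: bool = False,
) -> IterationResult:
    """Iteratively restrict the IbD window to [sigma, k_max * sigma].

    IbD slopes reflect recent dispersal only at distances within
    drift-dispersal equilibrium (roughly sigma to 10-50 sigma), so the
    window is re-derived from each successive sigma estimate until sigma
    changes by less than ``tol`` (relative) or ``max_iter`` is reached.
    ``k_max`` must lie in [10, 50].  ``density_fn`` optionally re-expresses
    density at the neighbourhood scale (called as density_fn(sigma) ->
    DensityEstimate).  When the window collapses below 3 pairs the last
    valid fit is returned flagged "scale-unresolved".
    """
    if not 10.0 <= k_max <= 50.0:
        raise ValueError("k_max must be within [10, 50]")
    d_lo, d_hi = float(np.nanmin(t.d)), float(np.nanmax(t.d))
    window = (d_lo, d_hi)
    history: list[dict] = []
    sigma_prev = None
    result_fit = None
    f1 = None
    flag = "max-iterations"
    for it in range(max_iter):
        try:
            fit = fit_ibd(t, window)
        except ValueError:
            flag = "scale-unresolved"
            break
        if t.metric_name == "loiselle_F":
            radius = sigma_prev if sigma_prev and np.isfinite(sigma_prev) else max(
                d_lo, float(np.nanpercentile(t.d, 5))
            )
            try:
                f1 = mean_kinship_first_class(t, radius)
            except ValueError:
                f1 = mean_kinship_first_class(t, d_hi)
        ns = ns_from_fit(fit, f1, literal_printed)
        dens = density_fn(sigma_prev) if (density_fn and sigma_prev) else density
        sigma = sigma_point(ns, dens.central)
        history.append(
            {"iteration": it, "window": window, "slope": fit.slope,
             "ns": ns, "f1": f1, "sigma": sigma}
        )
        result_fit = fit
        if not np.isfinite(sigma):
            flag = "scale-unresolved"
            sigma_prev = sigma
            break
        if sigma_prev is not None and np.isfinite(sigma_prev):
            if abs(sigma - sigma_prev) / sigma_prev < tol:
                sigma_prev = sigma
                flag = "converged"
                break
        new_window = (max(sigma, d_lo), min(k_max * sigma, d_hi))
        if new_window == window:
            sigma_prev = sigma
            flag = "converged"
            break
        window = new_window
        sigma_prev = sigma
    if result_fit is None:
        raise ValueError("no valid IbD fit at any window")
    return IterationResult(result_fit, float(sigma_prev), f1, history, flag)
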