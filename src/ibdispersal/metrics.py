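"""Individual pairwise genetic statistics and population summaries.

Two individual-level statistics drive the isolation-by-distance analysis:

* Rousset's a-hat — a genetic *distance* built from probabilities of allele
  identity in state, the individual-pair analogue of F_ST/(1 - F_ST).  It
  increases linearly with ln(distance) in a 2D population at drift-dispersal
  equilibrium, with slope 1/(4*pi*D*sigma^2).
* Loiselle's F — a kinship coefficient built from products of allele-
  frequency deviations with a finite-sample correction.  It decreases
  linearly with ln(distance); it is robust to inbreeding/selfing, which is
  why it is preferred when F_IS > 0.

Both are multilocus ratio-of-sums estimators: per-pair per-locus numerator
and denominator contributions are kept so confidence intervals can be
formed by resampling loci.

Population summaries (F_IS, F_ST) use Weir & Cockerham's variance
components, again combined across loci as ratios of sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class PairMetricTable:
    """Pairwise metric values with per-locus contributions for resampling.

    ``num`` and ``den`` are (n_pairs, n_loci) float64 arrays; the per-pair
    value is ``num.sum(1) / den.sum(1)`` (ratio of sums across loci).  Loci
    not co-typed for a pair contribute zero to both.
    """

    metric_name: str
    i: np.ndarray  # ids, shape (n_pairs,)
    j: np.ndarray
    d: np.ndarray  # metres (NaN when no spatial data)
    num: np.ndarray
    den: np.ndarray
    locus_ids: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.i)

    @property
    def n_loci(self) -> int:
        return self.num.shape[1]

    def values(self) -> np.ndarray:
        return self.num.sum(axis=1) / self.den.sum(axis=1)

    def subset(self, mask: np.ndarray) -> "PairMetricTable":
        return PairMetricTable(
            self.metric_name, self.i[mask], self.j[mask], self.d[mask],
            self.num[mask], self.den[mask], self.locus_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"i": self.i, "j": self.j, "d": self.d, self.metric_name: self.values()}
        )


def _resolve_pairs(table: GenotypeTable, pairs: pd.DataFrame | None):
    """Map a (i, j, d) pair frame onto row indices of the genotype table."""
    idx = {ind: k for k, ind in enumerate(table.individual_ids)}
    if pairs is None:
        n = table.n_ind
        iu, ju = np.triu_indices(n, k=1)
        ids = np.asarray(table.individual_ids)
        return iu, ju, ids[iu], ids[ju], np.full(iu.size, np.nan)
    keep = pairs["i"].isin(idx) & pairs["j"].isin(idx)
    p = pairs.loc[keep]
    ii = p["i"].map(idx).to_numpy()
    jj = p["j"].map(idx).to_numpy()
    return ii, jj, p["i"].to_numpy(), p["j"].to_numpy(), p["d"].to_numpy(dtype=float)


def _finalise(metric, ids_i, ids_j, d, num, den, locus_ids) -> PairMetricTable:
    tot_den = den.sum(axis=1)
    ok = tot_den > 0
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info(
            "%s: dropped %d pair(s) sharing no co-typed polymorphic locus",
            metric, n_drop,
        )
    return PairMetricTable(
        metric, ids_i[ok], ids_j[ok], d[ok], num[ok], den[ok], list(locus_ids)
    )


def loiselle_kinship(
    table: GenotypeTable, pairs: pd.DataFrame | None = None
) -> PairMetricTable:
    """Loiselle's kinship coefficient F for individual pairs.

    Per locus and allele, with p_il the individual allele frequency
    (dosage/2) and p_l the sample mean over the n_l typed individuals::

        num_l = sum_a (p_il - p_l)(p_jl - p_l) + p_l (1 - p_l) / (n_l - 1)
        den_l = sum_a p_l (1 - p_l)

    For biallelic loci both alleles contribute equal terms (factor 2).
    F_ij = sum_l num_l / sum_l den_l over loci co-typed for the pair.
    """
    if table.n_ind < 3:
        raise ValueError("need at least 3 individuals")
    g = table.genotypes.astype(np.float64)
    called = g != MISSING
    p = np.where(called, g / 2.0, np.nan)
    n_l = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        pbar = np.nanmean(p, axis=0)
    het = pbar * (1.0 - pbar)  # per-locus p(1-p)
    if not (np.nan_to_num(het) > 0).any():
        raise ValueError("zero denominator: no polymorphism at any locus")
    dev = np.where(called, p - pbar, 0.0)
    corr = np.where(n_l > 1, het / (n_l - 1.0), 0.0)

    ii, jj, ids_i, ids_j, d = _resolve_pairs(table, pairs)
    co = called[ii] & called[jj]
    num = 2.0 * (dev[ii] * dev[jj] + corr[None, :]) * co
    den = 2.0 * np.broadcast_to(het, co.shape) * co
    den = np.where(np.isnan(den), 0.0, den)
    num = np.where(np.isnan(num), 0.0, num)
    return _finalise("loiselle_F", ids_i, ids_j, d, num, den, table.locus_ids)


def rousset_a(
    table: GenotypeTable, pairs: pd.DataFrame | None = None
) -> PairMetricTable:
    """Rousset's a-hat genetic distance for individual pairs.

    Per locus, Q_w is the sample-average probability that an individual's
    two alleles are identical in state (the homozygote fraction among typed
    individuals) and Q_ij averages identity over the four cross-individual
    allele pairs.  a_ij = sum_l (Q_w,l - Q_ij,l) / sum_l (1 - Q_w,l) over
    co-typed loci.  Q_w is sample-wide (lower-variance plug-in).
    """
    if table.n_ind < 3:
        raise ValueError("need at least 3 individuals")
    g = table.genotypes.astype(np.float64)
    called = g != MISSING
    hom = np.where(called, (g == 0) | (g == 2), np.nan).astype(float)
    with np.errstate(invalid="ignore"):
        q_w = np.nanmean(np.where(called, hom, np.nan), axis=0)
    one_minus_qw = 1.0 - q_w
    if not (np.nan_to_num(one_minus_qw) > 0).any():
        raise ValueError(
            "all individuals fully homozygous at every locus: a-hat undefined"
        )
    ii, jj, ids_i, ids_j, d = _resolve_pairs(table, pairs)
    co = called[ii] & called[jj]
    gi = np.where(called[ii], g[ii], 0.0)
    gj = np.where(called[jj], g[jj], 0.0)
    q_ij = (gi * gj + (2.0 - gi) * (2.0 - gj)) / 4.0
    num = (q_w[None, :] - q_ij) * co
    den = np.broadcast_to(one_minus_qw, co.shape) * co
    num = np.where(np.isnan(num), 0.0, num)
    den = np.where(np.isnan(den), 0.0, den)
    return _finalise("rousset_a", ids_i, ids_j, d, num, den, table.locus_ids)


def mean_kinship_first_class(
    t: PairMetricTable, neighbour_radius: float
) -> float:
    """Mean kinship F(1) over pairs within ``neighbour_radius`` metres.

    F(1) rescales the kinship IbD slope into a neighbourhood size; the
    radius defaults (at call sites) to the current sigma estimate.
    """
    if t.metric_name != "loiselle_F":
        raise ValueError("F(1) is defined for Loiselle's F tables")
    mask = t.d <= neighbour_radius
    if not mask.any():
        raise ValueError(
            f"no pairs within {neighbour_radius} m; increase the radius"
        )
    return float(t.values()[mask].mean())


# ---------------------------------------------------------------------------
# Weir-Cockerham population summaries
# ---------------------------------------------------------------------------

def _wc_components(g: np.ndarray, pops: list[np.ndarray]):
    """WC84 per-locus variance components a, b, c for r >= 1 populations.

    ``pops`` is a list of row-index arrays.  Returns (a, b, c) arrays over
    loci; loci informative in fewer than 1 population or monomorphic overall
    contribute zeros.
    """
    r = len(pops)
    L = g.shape[1]
    n = np.zeros((r, L))
    p = np.zeros((r, L))
    h = np.zeros((r, L))
    for k, rows in enumerate(pops):
        sub = g[rows]
        called = sub != MISSING
        n[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(n[k] > 0, np.where(called, sub, 0).sum(axis=0) / (2 * n[k]), np.nan)
            h[k] = np.where(n[k] > 0, np.where(called, sub == 1, 0).sum(axis=0) / n[k], np.nan)
    ok = (n >= 2).all(axis=0)
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n * p).sum(axis=0) / (r * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        if r > 1:
            nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
            s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        else:
            nc = nbar
            s2 = np.zeros(L)
        pq = pbar * (1.0 - pbar)
        inner = pq - ((r - 1.0) / r) * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - (1.0 / (nbar - 1.0)) * inner) if r > 1 else np.zeros(L)
        b = (nbar / (nbar - 1.0)) * (pq - ((r - 1.0) / r) * s2 - ((2 * nbar - 1.0) / (4 * nbar)) * hbar)
        c = hbar / 2.0
    poly = ok & (pq > 0) & np.isfinite(pq)
    zero = ~poly
    for arr in (a, b, c):
        arr[zero] = 0.0
        arr[~np.isfinite(arr)] = 0.0
    return a, b, c


def fis(table: GenotypeTable, groups: dict[str, str]) -> dict[str, float]:
    """Weir-Cockerham within-population inbreeding coefficient per group.

    ``groups`` maps individual id -> group (location) label.  Multilocus
    ratio of sums; monomorphic groups report NaN.
    """
    out: dict[str, float] = {}
    labels = sorted(set(groups.get(i) for i in table.individual_ids) - {None})
    for lbl in labels:
        rows = np.array(
            [k for k, ind in enumerate(table.individual_ids) if groups.get(ind) == lbl]
        )
        if len(rows) < 2:
            out[lbl] = float("nan")
            continue
        _, b, c = _wc_components(table.genotypes, [rows])
        denom = (b + c).sum()
        out[lbl] = float(1.0 - c.sum() / denom) if denom > 0 else float("nan")
    return out


def fis_jackknife(table: GenotypeTable, groups: dict[str, str]) -> dict[str, tuple]:
    """Per-group F_IS with delete-one-locus jackknife 95% CI."""
    out = {}
    labels = sorted(set(groups.get(i) for i in table.individual_ids) - {None})
    for lbl in labels:
        rows = np.array(
            [k for k, ind in enumerate(table.individual_ids) if groups.get(ind) == lbl]
        )
        if len(rows) < 2:
            out[lbl] = (float("nan"), float("nan"), float("nan"))
            continue
        _, b, c = _wc_components(table.genotypes, [rows])
        B, C = b.sum(), c.sum()
        if B + C <= 0:
            out[lbl] = (float("nan"), float("nan"), float("nan"))
            continue
        point = 1.0 - C / (B + C)
        with np.errstate(invalid="ignore", divide="ignore"):
            loo = 1.0 - (C - c) / ((B - b) + (C - c))
        loo = loo[np.isfinite(loo)]
        L = len(loo)
        se = np.sqrt((L - 1) / L * ((loo - loo.mean()) ** 2).sum()) if L > 1 else 0.0
        out[lbl] = (float(point), float(point - 1.96 * se), float(point + 1.96 * se))
    return out


def fst_wc(table: GenotypeTable, groups: dict[str, str]) -> pd.DataFrame:
    """Pairwise Weir-Cockerham theta (F_ST) between groups.

    Multilocus ratio of sums of the WC84 a, b, c components.
    """
    labels = sorted(set(groups.get(i) for i in table.individual_ids) - {None})
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    rows_of = {
        lbl: np.array(
            [k for k, ind in enumerate(table.individual_ids) if groups.get(ind) == lbl]
        )
        for lbl in labels
    }
    recs = []
    for x in range(len(labels)):
        for y in range(x + 1, len(labels)):
            la, lb = labels[x], labels[y]
            a, b, c = _wc_components(table.genotypes, [rows_of[la], rows_of[lb]])
            denom = (a + b + c).sum()
            theta = float(a.sum() / denom) if denom > 0 else float("nan")
            recs.append({"pop1": la, "pop2": lb, "theta": theta})
    return pd.DataFrame(recs)
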