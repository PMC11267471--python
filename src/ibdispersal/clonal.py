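"""Clone (genet) detection from multilocus genotype distances.

Colonies of sessile clonal organisms can share a multilocus genotype
through fission or parthenogenesis.  Technical replicates (repeat samples
of one colony) bound the genotyping-error scale, which calibrates the
distance threshold below which two colonies are called ramets of one
genet.  Genets are the units of all downstream dispersal analysis: one
representative (lowest missingness) per genet is retained.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .data_model import MISSING, ColonyMap, GenotypeTable

logger = logging.getLogger(__name__)

#: pairs with fewer than this fraction of co-typed loci give unstable
#: distances and are excluded from threshold calibration
MIN_COTYPED_FRACTION = 0.2


@dataclass
class CloneAssignment:
    """Partition of sampled colonies into genets."""

    threshold: float
    genet_id: dict[str, int]
    representative: dict[int, str]
    n_genets: int
    n_colonies: int
    clone_pair_distances: list[float] = field(default_factory=list)

    @property
    def ng_over_n(self) -> float:
        return self.n_genets / self.n_colonies

    def representatives(self) -> list[str]:
        return sorted(self.representative.values())


def clonal_distance(table: GenotypeTable) -> np.ndarray:
    """Pairwise shared-allele (Prevosti-type) distance on dosages.

    Per co-typed locus the similarity is ``1 - |d_i - d_j| / 2``; the pair
    distance is one minus the mean similarity over co-typed loci, in [0, 1].
    Pairs with no co-typed locus get NaN (excluded downstream with a
    warning).  Diagonal is 0.
    """
    if table.n_ind < 2:
        raise ValueError("need at least 2 individuals")
    g = table.genotypes.astype(np.float64)
    called = g != MISSING
    gm = np.where(called, g, 0.0)
    c = called.astype(np.float64)
    # sum over co-typed loci of |d_i - d_j| via the identity
    # |a-b| expanded is awkward in matrix form; do it blockwise instead.
    n = table.n_ind
    dist = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(gm[i] - gm) / 2.0
        co = called[i] & called
        L = co.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist[i] = np.where(L > 0, (diff * co).sum(axis=1) / L, np.nan)
    np.fill_diagonal(dist, 0.0)
    if np.isnan(dist[np.triu_indices(n, 1)]).any():
        warnings.warn("pairs with zero co-typed loci: distance undefined (NaN)")
    return dist


def replicate_pairs(table: GenotypeTable) -> list[tuple[int, int]]:
    """Index pairs of technical replicates (same replicate_group label)."""
    groups: dict[str, list[int]] = {}
    for i, ind in enumerate(table.individual_ids):
        grp = table.replicate_group.get(ind)
        if grp is not None:
            groups.setdefault(grp, []).append(i)
    return [
        pair
        for members in groups.values()
        for pair in itertools.combinations(members, 2)
    ]


def calibrate_threshold(
    dists: np.ndarray,
    rep_pairs: list[tuple[int, int]],
    cotyped_fraction: np.ndarray | None = None,
) -> float:
    """Calibrate the clone-calling distance threshold on replicate pairs.

    Replicate pairs bound the genotyping-error distance scale.  True clone
    pairs are statistically indistinguishable from replicate pairs, so
    non-replicate distances near the replicate maximum are absorbed into
    the low (error-scale) mode by a walk-up rule: starting from the largest
    replicate distance, successive non-replicate distances are absorbed
    while they stay within a doubling (plus a small floor) of the current
    top.  The threshold is the midpoint of the first clear gap.  If the
    walk absorbs the entire distribution (no gap: error scale grades into
    unrelated pairs), fall back to the 95th percentile of replicate
    distances with a warning.  ``cotyped_fraction`` (same shape as dists)
    optionally masks unstable pairs from calibration.
    """
    if not rep_pairs:
        raise ValueError(
            "no technical-replicate pairs: supply a manual clone threshold"
        )
    n = dists.shape[0]
    rep_mask = np.zeros_like(dists, dtype=bool)
    for i, j in rep_pairs:
        rep_mask[i, j] = rep_mask[j, i] = True
    valid = ~np.isnan(dists)
    if cotyped_fraction is not None:
        valid &= cotyped_fraction >= MIN_COTYPED_FRACTION
    iu = np.triu_indices(n, 1)
    upper_valid = valid[iu]
    rep_d = dists[iu][rep_mask[iu] & upper_valid]
    non_d = dists[iu][~rep_mask[iu] & upper_valid]
    if rep_d.size == 0:
        raise ValueError("all replicate pairs excluded (missing data)")
    rep_max = float(rep_d.max())
    above = np.sort(non_d[non_d > rep_max])
    if above.size == 0:
        warnings.warn("no non-replicate distance above replicates; using replicate max")
        return rep_max
    # walk-up absorption of clone-like distances into the error-scale mode:
    # the low mode is the replicate distances plus presumptive clones at or
    # below rep_max; successive candidates are absorbed while each step
    # stays within the low mode's own spread
    low = np.concatenate([rep_d, non_d[non_d <= rep_max]])
    top = rep_max
    spread = max(float(low.max() - low.min()), 0.5 * rep_max, 0.01)
    for c in above:
        if c - top <= spread:
            top = float(c)
        else:
            return float((top + c) / 2.0)
    warnings.warn(
        "replicate and non-replicate distances overlap (no clear gap); "
        "using 95th percentile of replicate distances"
    )
    return float(np.percentile(rep_d, 95))


def call_clones(
    table: GenotypeTable,
    dists: np.ndarray,
    threshold: float,
    cmap: ColonyMap | None = None,
) -> CloneAssignment:
    """Group colonies into genets by single-linkage at ``threshold``.

    Genets are connected components of the graph linking pairs at distance
    <= threshold; technical replicates are always co-grouped (they defined
    the threshold).  Representatives have minimal missingness (ties broken
    by id order).  ``clone_pair_distances`` are 2D spatial distances between
    distinct colonies within a genet (technical replicates of one colony
    collapse to a single colony first).
    """
    n = table.n_ind
    adj = np.nan_to_num(dists, nan=np.inf) <= threshold
    for i, j in replicate_pairs(table):
        adj[i, j] = adj[j, i] = True
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)

    ids = table.individual_ids
    miss = table.missing_fraction_per_individual()
    genet_id = {ind: int(lbl) for ind, lbl in zip(ids, labels)}

    representative: dict[int, str] = {}
    for lbl in np.unique(labels):
        members = [i for i in range(n) if labels[i] == lbl]
        best = min(members, key=lambda i: (miss[i], ids[i]))
        representative[int(lbl)] = ids[best]

    # collapse technical replicates to colonies
    colony_of = {
        ind: table.replicate_group.get(ind, ind) for ind in ids
    }
    colonies = sorted(set(colony_of.values()))
    n_colonies = len(colonies)
    colony_genet = {}
    for ind in ids:
        colony_genet.setdefault(colony_of[ind], genet_id[ind])
    n_genets = len(set(colony_genet.values()))

    clone_pair_d: list[float] = []
    if cmap is not None:
        pos = {
            r.id: (r.x, r.y) for r in cmap.table.itertuples()
        }
        by_genet: dict[int, list[str]] = {}
        for colony, g in colony_genet.items():
            by_genet.setdefault(g, []).append(colony)
        for members in by_genet.values():
            for a, b in itertools.combinations(sorted(members), 2):
                if a in pos and b in pos:
                    clone_pair_d.append(
                        float(np.hypot(pos[a][0] - pos[b][0], pos[a][1] - pos[b][1]))
                    )

    assign = CloneAssignment(
        threshold=threshold,
        genet_id=genet_id,
        representative=representative,
        n_genets=n_genets,
        n_colonies=n_colonies,
        clone_pair_distances=clone_pair_d,
    )
    logger.info(
        "clone calling: %d colonies -> %d genets (Ng:N = %.2f) at t = %.4f",
        n_colonies, n_genets, assign.ng_over_n, threshold,
    )
    return assign


def clonal_spatial_summary(assign: CloneAssignment) -> dict:
    """Summarise clone-pair spatial distances (median, fraction <= 1 m)."""
    d = np.asarray(assign.clone_pair_distances, dtype=float)
    if d.size == 0:
        return {"n_pairs": 0, "empty": True}
    return {
        "n_pairs": int(d.size),
        "empty": False,
        "median_m": float(np.median(d)),
        "fraction_within_1m": float((d <= 1.0).mean()),
        "distances_m": d.tolist(),
    }


def cotyped_fraction(table: GenotypeTable) -> np.ndarray:
    """Fraction of loci co-typed for every pair (symmetric matrix)."""
    called = (table.genotypes != MISSING).astype(np.float64)
    co = called @ called.T
    return co / table.n_loci
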