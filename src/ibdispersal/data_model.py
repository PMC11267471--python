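"""Core data structures and spatial/genotype plumbing.

Genotypes are diploid biallelic SNP calls stored as allele dosages
(0 = homozygous reference, 1 = heterozygous, 2 = homozygous alternate,
-1 = missing) in an ``n_individuals x n_loci`` int8 matrix.  Colony
positions live in a tidy table (id, location, plot, x, y, z in metres);
all spatial analysis happens on 2D within-location Euclidean distances
after per-plot flattening.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MISSING = -1

#: Smallest analysed pair distance (m); coincident colonies are floored here.
DISTANCE_FLOOR = 0.01


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass
class GenotypeTable:
    """Individuals x biallelic loci dosage matrix with locus metadata.

    Parameters
    ----------
    individual_ids : list of str
        Unique sample identifiers, in file order.
    genotypes : ndarray of int8, shape (n_ind, n_loci)
        Allele dosages; ``-1`` marks a missing call.
    locus_ids : list of str
        Locus names (e.g. ``contig:pos``).
    contig_ids : list of str
        RAD contig (CHROM) per locus; used for physical-linkage thinning.
    replicate_group : dict, optional
        ``individual_id -> group label``; individuals sharing a label are
        technical replicates of one colony.
    taxon : dict, optional
        ``individual_id -> taxon label``.
    """

    individual_ids: list[str]
    genotypes: np.ndarray
    locus_ids: list[str]
    contig_ids: list[str]
    replicate_group: dict[str, str] = field(default_factory=dict)
    taxon: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_ind, n_loci = self.genotypes.shape
        if n_ind < 1 or n_loci < 1:
            raise ValueError("genotype matrix must be at least 1 x 1")
        if len(self.individual_ids) != n_ind:
            raise ValueError("individual_ids length mismatch")
        if len(set(self.individual_ids)) != n_ind:
            raise ValueError("duplicate individual ids")
        if len(self.locus_ids) != n_loci or len(self.contig_ids) != n_loci:
            raise ValueError("locus metadata length mismatch")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0/1/2 or -1 (missing)")

    # -- basic accessors -------------------------------------------------
    @property
    def n_ind(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def missing_fraction_per_individual(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    def missing_fraction_per_locus(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=0)

    def minor_allele_count(self) -> np.ndarray:
        """Minor-allele count per locus over non-missing calls."""
        g = self.genotypes
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        return np.minimum(alt, total - alt)

    def take_individuals(self, idx: np.ndarray | list[int]) -> "GenotypeTable":
        idx = np.asarray(idx)
        ids = [self.individual_ids[i] for i in idx]
        return GenotypeTable(
            ids,
            self.genotypes[idx],
            list(self.locus_ids),
            list(self.contig_ids),
            {i: self.replicate_group[i] for i in ids if i in self.replicate_group},
            {i: self.taxon[i] for i in ids if i in self.taxon},
        )

    def take_loci(self, idx: np.ndarray | list[int]) -> "GenotypeTable":
        idx = np.asarray(idx)
        return GenotypeTable(
            list(self.individual_ids),
            self.genotypes[:, idx],
            [self.locus_ids[i] for i in idx],
            [self.contig_ids[i] for i in idx],
            dict(self.replicate_group),
            dict(self.taxon),
        )


@dataclass
class ColonyMap:
    """Per-colony spatial records: id, location, plot, x/y/z in metres."""

    table: pd.DataFrame

    REQUIRED = ("id", "location", "plot", "x", "y", "z")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ParseError(f"colony map missing column(s): {missing}")
        if self.table["id"].duplicated().any():
            dups = self.table.loc[self.table["id"].duplicated(), "id"].tolist()
            raise ParseError(f"duplicate colony ids: {dups}")
        xyz = self.table[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(xyz).all():
            raise ParseError("non-finite coordinate in colony map")
        if (self.table["z"].to_numpy(dtype=float) < 0).any():
            raise ValueError("z (depth) must be >= 0")
        self.table = self.table.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def coords(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)


@dataclass
class FilterConfig:
    """Thresholds for the genotype-matrix filtering cascade.

    Individuals with more than ``max_ind_missing`` missing calls are
    dropped first; loci then need a minor-allele count of at least
    ``min_allele_count`` and at most ``max_snp_missing`` missingness.
    Depth filters only apply when a VCF carries per-call depth.
    """

    max_ind_missing: float = 0.5
    min_allele_count: int = 3
    max_snp_missing: float = 0.5
    min_depth: int | None = None
    max_depth_factor: float | None = None
    one_per_contig_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_ind_missing", "max_snp_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_allele_count < 1:
            raise ValueError("min_allele_count must be >= 1")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(
    path: str,
    replicate_map: str | None = None,
    min_depth: int | None = None,
    max_depth_factor: float | None = None,
) -> GenotypeTable:
    """Read a VCF (biallelic SNPs, GT field) or a genotype TSV.

    The TSV dialect is: header ``id<TAB>locus1<TAB>locus2...``, one row per
    individual, dosage symbols ``0/1/2`` and ``.`` for missing.  Locus names
    of the form ``contig:pos`` yield the contig id; otherwise the locus name
    is its own contig.  ``replicate_map`` is an optional TSV with columns
    ``id``, ``replicate_group`` and (optionally) ``taxon``.
    """
    if str(path).endswith((".vcf", ".vcf.gz")):
        table = _read_vcf(path, min_depth, max_depth_factor)
    else:
        table = _read_genotype_tsv(path)
    if replicate_map is not None:
        rep = pd.read_csv(replicate_map, sep="\t", dtype=str)
        if "id" not in rep.columns:
            raise ParseError("replicate map needs an 'id' column")
        if "replicate_group" in rep.columns:
            table.replicate_group.update(
                {r.id: r.replicate_group for r in rep.itertuples() if pd.notna(r.replicate_group)}
            )
        if "taxon" in rep.columns:
            table.taxon.update({r.id: r.taxon for r in rep.itertuples() if pd.notna(r.taxon)})
    return table


def _read_vcf(path: str, min_depth=None, max_depth_factor=None) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ParseError("duplicate sample ids in VCF header")
    rows, locus_ids, contig_ids, depths = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ParseError(
                f"multi-allelic record at {var.CHROM}:{var.POS} "
                "(split or drop multi-allelic sites first)"
            )
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.asarray(var.gt_types)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(dos.astype(np.int8))
        locus_ids.append(f"{var.CHROM}:{var.POS}")
        contig_ids.append(var.CHROM)
        if min_depth is not None or max_depth_factor is not None:
            try:
                dp = var.format("DP")
                depths.append(None if dp is None else dp[:, 0].astype(float))
            except Exception:
                depths.append(None)
    if not rows:
        raise ParseError(f"no variant records in {path}")
    geno = np.vstack(rows).T.astype(np.int8)
    if (min_depth is not None or max_depth_factor is not None):
        if any(d is None for d in depths):
            logger.info("depth filters requested but FORMAT/DP absent; skipping")
        else:
            dp = np.vstack(depths).T  # n_ind x n_loci
            mask = np.zeros_like(geno, dtype=bool)
            if min_depth is not None:
                mask |= dp < min_depth
            if max_depth_factor is not None:
                mask |= dp > max_depth_factor * np.nanmean(dp)
            geno = np.where(mask, MISSING, geno).astype(np.int8)
    return GenotypeTable(samples, geno, locus_ids, contig_ids)


def _read_genotype_tsv(path: str) -> GenotypeTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise ParseError(f"{path}: first header column must be 'id'")
        locus_ids = header[1:]
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields")
            ids.append(parts[0])
            try:
                rows.append([MISSING if p == "." else int(p) for p in parts[1:]])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: bad dosage symbol ({e})") from e
    contig_ids = [l.rsplit(":", 1)[0] if ":" in l else l for l in locus_ids]
    return GenotypeTable(ids, np.asarray(rows, dtype=np.int8), locus_ids, contig_ids)


def write_genotype_tsv(table: GenotypeTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(table.locus_ids) + "\n")
        for i, ind in enumerate(table.individual_ids):
            row = ["." if d == MISSING else str(d) for d in table.genotypes[i]]
            fh.write(ind + "\t" + "\t".join(row) + "\n")


def write_vcf(table: GenotypeTable, path: str) -> None:
    """Write a minimal VCF v4.2 (GT only) for the dosage matrix."""
    gt_sym = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in dict.fromkeys(table.contig_ids):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.individual_ids)
            + "\n"
        )
        for l, (locus, contig) in enumerate(zip(table.locus_ids, table.contig_ids)):
            pos = locus.rsplit(":", 1)[1] if ":" in locus else str(l + 1)
            calls = "\t".join(gt_sym[int(d)] for d in table.genotypes[:, l])
            fh.write(f"{contig}\t{pos}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def read_colony_map(path: str, genotyped_ids: list[str] | None = None) -> ColonyMap:
    """Read a colony-coordinate TSV (id, location, plot, x, y, z).

    Warns about genotyped individuals lacking coordinates; they are simply
    absent from spatial analyses.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "location": str, "plot": str})
    for col in ("x", "y", "z"):
        if col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                raise ParseError(
                    f"{path}: non-numeric {col} at row(s) {list(df.index[bad] + 2)}"
                )
            df[col] = pd.to_numeric(df[col])
    cmap = ColonyMap(df)
    if genotyped_ids is not None:
        missing = sorted(set(genotyped_ids) - set(cmap.ids))
        if missing:
            warnings.warn(
                f"{len(missing)} genotyped individual(s) lack coordinates and are "
                f"excluded from spatial analyses (e.g. {missing[:5]})"
            )
    return cmap


def write_colony_map(cmap: ColonyMap, path: str) -> None:
    cmap.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Coordinate handling
# ---------------------------------------------------------------------------

def load_plot_transforms(path: str) -> dict:
    """Load per-plot affine transforms from YAML.

    Each plot entry may define ``scale`` (scalar > 0), ``rotation_deg``
    (about the vertical axis) and ``translate`` ([dx, dy, dz] metres).
    """
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def transform_coordinates(cmap: ColonyMap, plot_transforms: dict) -> ColonyMap:
    """Express plot-local coordinates in the common survey frame.

    By convention x increases along shore between locations and y runs along
    the 25 m plot axis; plots of one location are offset along y/z.
    """
    df = cmap.table.copy()
    for plot, sub in df.groupby("plot"):
        if plot not in plot_transforms:
            raise ValueError(f"no transform for plot {plot!r}")
        tr = plot_transforms[plot] or {}
        scale = float(tr.get("scale", 1.0))
        if scale <= 0:
            raise ValueError(f"plot {plot!r}: scale must be > 0")
        theta = np.deg2rad(float(tr.get("rotation_deg", 0.0)))
        dx, dy, dz = (float(v) for v in tr.get("translate", (0.0, 0.0, 0.0)))
        xy = sub[["x", "y"]].to_numpy(dtype=float) * scale
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy = xy @ rot.T
        df.loc[sub.index, "x"] = xy[:, 0] + dx
        df.loc[sub.index, "y"] = xy[:, 1] + dy
        df.loc[sub.index, "z"] = sub["z"].to_numpy(dtype=float) * scale + dz
    return ColonyMap(df)


def flatten_plots(cmap: ColonyMap) -> ColonyMap:
    """Remove each plot's out-of-plane component (best-fit plane by SVD).

    The projection stays in the common frame (plot centroids are kept), so
    between-plot offsets survive; the residual normal component is dropped
    and subsequent analyses use (x, y) only.
    """
    df = cmap.table.copy()
    for _, sub in df.groupby("plot"):
        xyz = sub[["x", "y", "z"]].to_numpy(dtype=float)
        if len(sub) < 3:
            continue  # plane undefined; leave as-is
        centred = xyz - xyz.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        normal = vt[-1]
        flat = xyz - np.outer(centred @ normal, normal)
        df.loc[sub.index, ["x", "y", "z"]] = flat
    return ColonyMap(df)


def pairwise_distance_2d(
    cmap: ColonyMap, distance_floor: float = DISTANCE_FLOOR
) -> pd.DataFrame:
    """Within-location 2D Euclidean distances between colony centroids.

    Returns a DataFrame with columns ``i``, ``j`` (colony ids, i < j in table
    order), ``location`` and ``d`` (metres).  Cross-location pairs are
    excluded; coincident distinct colonies are floored at ``distance_floor``
    with a warning.
    """
    frames = []
    for loc, sub in cmap.table.groupby("location", sort=False):
        ids = sub["id"].to_numpy()
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        n = len(ids)
        if n < 2:
            continue
        iu, ju = np.triu_indices(n, k=1)
        d = np.hypot(xy[iu, 0] - xy[ju, 0], xy[iu, 1] - xy[ju, 1])
        n_floor = int((d < distance_floor).sum())
        if n_floor:
            warnings.warn(
                f"location {loc!r}: {n_floor} coincident/near-coincident pair(s) "
                f"floored at {distance_floor} m"
            )
            d = np.maximum(d, distance_floor)
        frames.append(
            pd.DataFrame({"i": ids[iu], "j": ids[ju], "location": loc, "d": d})
        )
    if not frames:
        return pd.DataFrame(columns=["i", "j", "location", "d"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_genotypes(table: GenotypeTable, cfg: FilterConfig | None = None):
    """Apply the filtering cascade: individuals first, then loci.

    Returns ``(filtered_table, report)`` where the report dict counts what
    each step removed, in application order.
    """
    cfg = cfg or FilterConfig()
    report: dict[str, int | float] = {
        "n_ind_in": table.n_ind,
        "n_loci_in": table.n_loci,
    }
    ind_keep = np.flatnonzero(
        table.missing_fraction_per_individual() <= cfg.max_ind_missing
    )
    report["individuals_removed_missing"] = table.n_ind - len(ind_keep)
    if len(ind_keep) == 0:
        raise ValueError("all data filtered: every individual exceeds missingness cap")
    t = table.take_individuals(ind_keep)

    mac_ok = t.minor_allele_count() >= cfg.min_allele_count
    report["loci_removed_mac"] = int((~mac_ok).sum())
    miss_ok = t.missing_fraction_per_locus() <= cfg.max_snp_missing
    report["loci_removed_missing"] = int((mac_ok & ~miss_ok).sum())
    loci_keep = np.flatnonzero(mac_ok & miss_ok)
    if len(loci_keep) == 0:
        raise ValueError("all data filtered: no locus passes MAC/missingness")
    t = t.take_loci(loci_keep)
    report["n_ind_out"] = t.n_ind
    report["n_loci_out"] = t.n_loci
    logger.info("filter report: %s", report)
    return t, report


def thin_one_snp_per_contig(table: GenotypeTable, seed: int = 0) -> GenotypeTable:
    """Keep exactly one SNP per contig, chosen uniformly with ``seed``."""
    rng = np.random.default_rng(seed)
    by_contig: dict[str, list[int]] = {}
    for l, c in enumerate(table.contig_ids):
        by_contig.setdefault(c, []).append(l)
    keep = sorted(int(rng.choice(loci)) for loci in by_contig.values())
    return table.take_loci(keep)
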