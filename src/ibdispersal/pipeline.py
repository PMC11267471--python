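"""End-to-end driver: genotypes + coordinates -> dispersal distance.

Stages run in the order of the underlying analysis: read, filter, clone
calling, linkage thinning, F_IS-guided metric choice, IbD regression with
locus-resampling CIs, iterative spatial-scale adjustment, and Monte-Carlo
sigma distributions per density kind.  Every stochastic stage records its
seed; each stage logs counts in and out so filtering provenance is
auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clonal, data_model, dispersal, ibd, metrics
from .data_model import FilterConfig
from .simulate import SimConfig, SimOutput, add_genotyping_noise, sample_plots, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one per-taxon pipeline run."""

    genotypes: str
    colony_map: str
    out_dir: str
    replicate_map: str | None = None
    transforms: str | None = None
    densities: str | None = None
    taxon: str | None = None
    metric: str = "auto"  # rousset_a | loiselle_F | both | auto
    window_policy: str = "iterative"  # fixed | iterative
    window: tuple[float, float] | None = None
    k_max: float = 20.0
    n_boot: int = 1000
    n_draws: int = 2000
    seed: int = 0
    clone_threshold: float | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        filt = FilterConfig(**raw.pop("filter", {}))
        return cls(filter=filt, **raw)


def _load_densities(cfg: RunConfig, assign, cmap) -> list[dispersal.DensityEstimate]:
    out = []
    if cfg.densities is None:
        return out
    with open(cfg.densities) as fh:
        spec = yaml.safe_load(fh) or {}
    if "census" in spec:
        plot_areas = {str(k): float(v) for k, v in spec["census"]["plot_areas"].items()}
        plot_of = dict(zip(cmap.table["id"], cmap.table["plot"]))
        genets_per_plot: dict[str, set] = {p: set() for p in plot_areas}
        for ind, g in assign.genet_id.items():
            p = plot_of.get(ind)
            if p in genets_per_plot:
                genets_per_plot[p].add(g)
        out.append(
            dispersal.census_density(
                {p: len(s) for p, s in genets_per_plot.items()}, plot_areas
            )
        )
    if "effective" in spec:
        eff = spec["effective"]
        out.append(
            dispersal.effective_density(
                float(eff["ne"]), tuple(float(v) for v in eff["ne_ci"]),
                float(eff["area_m2"]),
            )
        )
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full taxon -> sigma analysis; returns the report dict."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "config": _config_dict(cfg)}
    stage = "read"
    try:
        table = data_model.read_genotypes(cfg.genotypes, cfg.replicate_map)
        if cfg.taxon is not None and table.taxon:
            idx = [k for k, i in enumerate(table.individual_ids)
                   if table.taxon.get(i) == cfg.taxon]
            if not idx:
                raise ValueError(f"no individuals labelled taxon {cfg.taxon!r}")
            table = table.take_individuals(idx)
        cmap = data_model.read_colony_map(cfg.colony_map, table.individual_ids)
        if cfg.transforms:
            cmap = data_model.transform_coordinates(
                cmap, data_model.load_plot_transforms(cfg.transforms)
            )
        cmap = data_model.flatten_plots(cmap)
        logger.info("read: %d individuals, %d loci", table.n_ind, table.n_loci)

        stage = "filter"
        table, filt_report = data_model.filter_genotypes(table, cfg.filter)
        report["filter"] = filt_report

        stage = "clones"
        dists = clonal.clonal_distance(table)
        rep_pairs = clonal.replicate_pairs(table)
        if cfg.clone_threshold is not None:
            threshold = cfg.clone_threshold
        else:
            threshold = clonal.calibrate_threshold(
                dists, rep_pairs, clonal.cotyped_fraction(table)
            )
        assign = clonal.call_clones(table, dists, threshold, cmap)
        report["clones"] = {
            "threshold": threshold,
            "n_colonies": assign.n_colonies,
            "n_genets": assign.n_genets,
            "ng_over_n": assign.ng_over_n,
            "spatial": clonal.clonal_spatial_summary(assign),
        }
        reps = assign.representatives()
        keep = [k for k, i in enumerate(table.individual_ids) if i in set(reps)]
        table = table.take_individuals(keep)

        stage = "thin"
        table = data_model.thin_one_snp_per_contig(table, cfg.filter.one_per_contig_seed)
        report["thin"] = {"n_loci": table.n_loci}

        stage = "metrics"
        locations = dict(zip(cmap.table["id"], cmap.table["location"]))
        fis_ci = metrics.fis_jackknife(table, locations)
        report["fis"] = {k: list(v) for k, v in fis_ci.items()}
        inbred = any(np.isfinite(lo) and lo > 0 for (_, lo, _) in fis_ci.values())
        if cfg.metric == "auto":
            chosen = ["loiselle_F"] if inbred else ["rousset_a"]
        elif cfg.metric == "both":
            chosen = ["rousset_a", "loiselle_F"]
        else:
            chosen = [cfg.metric]
        report["metrics_used"] = chosen

        pairs = data_model.pairwise_distance_2d(cmap)
        pairs = pairs[pairs["i"].isin(set(table.individual_ids))
                      & pairs["j"].isin(set(table.individual_ids))]
        densities = _load_densities(cfg, assign, cmap)
        report["densities"] = [
            {"kind": d.kind, "central": d.central, "ci": [d.ci_low, d.ci_high]}
            for d in densities
        ]

        stage = "ibd"
        report["fits"] = {}
        report["sigma"] = {}
        for metric_name in chosen:
            fn = metrics.rousset_a if metric_name == "rousset_a" else metrics.loiselle_kinship
            t = fn(table, pairs)
            for dens in densities or [None]:
                key = f"{metric_name}/{dens.kind if dens else 'none'}"
                if dens is None:
                    fit = ibd.bootstrap_ci_loci(t, n_boot=cfg.n_boot, seed=cfg.seed)
                    report["fits"][key] = fit.to_dict()
                    continue
                if cfg.window_policy == "iterative":
                    it = dispersal.iterate_sigma(t, dens, k_max=cfg.k_max)
                    window, f1 = it.fit.window, it.f1
                    flag = it.flag
                else:
                    window = cfg.window or (float(np.nanmin(t.d)), float(np.nanmax(t.d)))
                    f1 = (metrics.mean_kinship_first_class(
                        t, float(np.nanpercentile(t.d, 5)))
                        if metric_name == "loiselle_F" else None)
                    flag = "fixed"
                fit = ibd.bootstrap_ci_loci(t, window, cfg.n_boot, cfg.seed)
                report["fits"][key] = {**fit.to_dict(), "scale_flag": flag}
                sig_ok = (fit.significant
                          and ((metric_name == "rousset_a" and fit.slope > 0)
                               or (metric_name == "loiselle_F" and fit.slope < 0)))
                if not sig_ok:
                    report["sigma"][key] = {"flag": "no significant IbD slope"}
                    continue
                src = dispersal.NSSource.from_slopes(fit, f1)
                est = dispersal.sigma_distribution(src, dens, cfg.n_draws, cfg.seed)
                report["sigma"][key] = est.to_dict()
    except Exception as err:
        report["error"] = {"stage": stage, "message": str(err)}
        _write_report(report, out_dir)
        raise
    _write_report(report, out_dir)
    _write_summary_row(report, out_dir, cfg)
    return report


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _write_report(report: dict, out_dir: Path) -> None:
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)


def _write_summary_row(report: dict, out_dir: Path, cfg: RunConfig) -> None:
    rows = []
    for key, sig in report.get("sigma", {}).items():
        metric, kind = key.split("/")
        fit = report["fits"].get(key, {})
        rows.append({
            "taxon": cfg.taxon or "all",
            "metric": metric,
            "density": kind,
            "slope": fit.get("slope"),
            "ns": (dispersal.ns_from_rousset(fit["slope"])
                   if metric == "rousset_a" and fit.get("slope") else None),
            "sigma_median_m": sig.get("median_m"),
            "sigma_pi90_m": str(sig.get("pi_90_m")),
            "flag": sig.get("flag"),
        })
    pd.DataFrame(rows).to_csv(out_dir / "summary.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_fixtures(size: str, seed: int, out_dir: str,
                  n: int | None = None, n_loci: int | None = None) -> dict:
    """Write a self-contained test dataset (VCF, colony map, truth JSON).

    ``tiny`` builds in seconds (40 individuals, 50 loci); ``paper-scale``
    matches the magnitude of a real single-taxon RADseq dataset (300
    individuals, 1500 loci).  Regenerates identically from the seed.
    """
    presets = {"tiny": (40, 50), "paper-scale": (300, 1500)}
    if size not in presets:
        raise ValueError(f"size must be one of {sorted(presets)}")
    n = n or presets[size][0]
    n_loci = n_loci or presets[size][1]
    # plots cover 300 of 3600 m^2, so ~n/12 of the population lands in them;
    # 16x gives comfortable margin before trimming to exactly n
    cfg = SimConfig(
        arena=(60.0, 60.0), n_individuals=max(24 * n, 600), sigma_true=2.0,
        n_loci=n_loci, generations=20 if size == "tiny" else 40,
        clonal_rate=0.1, snps_per_contig=3, seed=seed,
    )
    out = simulate(cfg)
    plots = {"P1": (5.0, 10.0, 25.0, 4.0), "P2": (25.0, 40.0, 25.0, 4.0),
             "P3": (5.0, 25.0, 25.0, 4.0)}
    out = sample_plots(out, plots)
    base = out.genotypes.individual_ids
    if len(base) < n:
        raise RuntimeError(
            f"plots captured {len(base)} < {n} individuals; widen the plots"
        )
    # trim to the exact requested size before layering on noise so the
    # technical-replicate samples always survive
    keep = set(base[:n])
    idx = [k for k, i in enumerate(base) if i in keep]
    cm = out.colony_map.table
    trimmed = SimOutput(
        out.genotypes.take_individuals(idx),
        data_model.ColonyMap(cm[cm["id"].isin(keep)].reset_index(drop=True)),
        out.truth,
    )
    out = add_genotyping_noise(trimmed, 0.005, 0.05,
                               n_replicate_samples=max(3, n // 20),
                               seed=seed + 1)
    table = out.genotypes
    path = Path(out_dir)
    path.mkdir(parents=True, exist_ok=True)
    data_model.write_vcf(table, str(path / "genotypes.vcf"))
    data_model.write_colony_map(out.colony_map, str(path / "colonies.tsv"))
    with open(path / "replicates.tsv", "w") as fh:
        fh.write("id\treplicate_group\ttaxon\n")
        for ind in table.individual_ids:
            grp = table.replicate_group.get(ind, "")
            fh.write(f"{ind}\t{grp}\t{table.taxon.get(ind, 'sim')}\n")
    truth = {
        "sigma_true": out.truth["sigma_true"],
        "density_true": out.truth["density_true"],
        "genet_of": {i: out.truth["genet_of"][i] for i in table.individual_ids
                     if i in out.truth["genet_of"]},
        "plot_areas": out.truth.get("plot_areas", {}),
        "seed": seed,
    }
    with open(path / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return {"n_individuals": len(table.individual_ids), "n_loci": table.n_loci,
            "dir": str(path)}
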