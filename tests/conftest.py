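"""Shared fixtures: toy tables and reusable simulated datasets."""

import numpy as np
import pandas as pd
import pytest

from ibdispersal.data_model import ColonyMap, GenotypeTable
from ibdispersal.simulate import SimConfig, sample_plots, simulate


def make_table(geno, rep=None, taxon=None, contig_per_locus=None):
    """Build a GenotypeTable from a plain dosage list-of-lists."""
    geno = np.asarray(geno, dtype=np.int8)
    n, L = geno.shape
    ids = [f"i{k}" for k in range(n)]
    contigs = contig_per_locus or [f"c{l}" for l in range(L)]
    loci = [f"{c}:{l}" for l, c in enumerate(contigs)]
    return GenotypeTable(ids, geno, loci, contigs,
                         replicate_group=rep or {}, taxon=taxon or {})


def make_colony_map(coords, location="L1", plot="P1"):
    """coords: dict id -> (x, y) or (x, y, z)."""
    rows = []
    for cid, xy in coords.items():
        x, y, *rest = xy
        rows.append({"id": cid, "location": location, "plot": plot,
                     "x": x, "y": y, "z": rest[0] if rest else 0.0})
    return ColonyMap(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_sim():
    """A medium forward simulation reused across read-only tests."""
    cfg = SimConfig(arena=(50.0, 50.0), n_individuals=600, sigma_true=2.0,
                    n_loci=200, generations=30, seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def sampled_sim(small_sim):
    plots = {"P1": (5.0, 5.0, 25.0, 4.0), "P2": (15.0, 30.0, 25.0, 4.0)}
    return sample_plots(small_sim, plots)
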