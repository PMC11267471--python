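"""Pairwise statistics against independent brute-force oracles."""

import numpy as np
import pytest

from ibdispersal.data_model import MISSING
from ibdispersal.metrics import (
    fis,
    fst_wc,
    loiselle_kinship,
    mean_kinship_first_class,
    rousset_a,
)

from .conftest import make_table

# ---------------------------------------------------------------------------
# Brute-force oracles: plain-python, term-by-term, independent of the
# vectorised implementation.
# ---------------------------------------------------------------------------

def brute_loiselle(geno, i, j):
    geno = np.asarray(geno, dtype=float)
    n, L = geno.shape
    num = den = 0.0
    for l in range(L):
        typed = [k for k in range(n) if geno[k, l] != MISSING]
        if geno[i, l] == MISSING or geno[j, l] == MISSING or len(typed) < 2:
            continue
        n_l = len(typed)
        for allele in (0, 1):  # both alleles of the biallelic locus
            p = [geno[k, l] / 2.0 for k in typed]
            if allele == 0:
                p = [1.0 - v for v in p]
            pbar = sum(p) / n_l
            p_i = (geno[i, l] / 2.0) if allele == 1 else 1.0 - geno[i, l] / 2.0
            p_j = (geno[j, l] / 2.0) if allele == 1 else 1.0 - geno[j, l] / 2.0
            num += (p_i - pbar) * (p_j - pbar) + pbar * (1 - pbar) / (n_l - 1)
            den += pbar * (1 - pbar)
    return num / den


def brute_rousset(geno, i, j):
    geno = np.asarray(geno, dtype=float)
    n, L = geno.shape

    def alleles(d):
        return [1, 1] if d == 2 else ([0, 0] if d == 0 else [0, 1])

    num = den = 0.0
    for l in range(L):
        typed = [k for k in range(n) if geno[k, l] != MISSING]
        if geno[i, l] == MISSING or geno[j, l] == MISSING or not typed:
            continue
        q_w = sum(1.0 for k in typed if geno[k, l] in (0, 2)) / len(typed)
        ai, aj = alleles(geno[i, l]), alleles(geno[j, l])
        q_ij = sum(1.0 for x in ai for y in aj if x == y) / 4.0
        num += q_w - q_ij
        den += 1.0 - q_w
    return num / den


TOY_TABLES = [
    # 4 individuals x 2 loci, complete
    [[0, 1], [1, 2], [2, 0], [1, 1]],
    # 4 x 3 with heterozygotes and homozygotes
    [[0, 0, 1], [2, 1, 1], [1, 2, 0], [0, 1, 2]],
    # missing data exercises co-typing and sample-wide frequencies
    [[0, MISSING, 1], [1, 1, MISSING], [2, 0, 1], [MISSING, 2, 2]],
]


class TestOracles:
    @pytest.mark.parametrize("geno", TOY_TABLES)
    def test_loiselle_matches_brute_force(self, geno):
        t = make_table(geno)
        table = loiselle_kinship(t)
        vals = table.values()
        for k in range(table.n_pairs):
            i = t.individual_ids.index(table.i[k])
            j = t.individual_ids.index(table.j[k])
            assert vals[k] == pytest.approx(brute_loiselle(geno, i, j), abs=1e-12)

    @pytest.mark.parametrize("geno", TOY_TABLES)
    def test_rousset_matches_brute_force(self, geno):
        t = make_table(geno)
        table = rousset_a(t)
        vals = table.values()
        for k in range(table.n_pairs):
            i = t.individual_ids.index(table.i[k])
            j = t.individual_ids.index(table.j[k])
            assert vals[k] == pytest.approx(brute_rousset(geno, i, j), abs=1e-12)

    def test_deviation_sum_identity(self):
        """Without the finite-sample term, ordered-pair numerators sum to
        minus the squared deviations, exactly (complete data)."""
        geno = np.array([[0, 1], [1, 2], [2, 0], [1, 1], [0, 2]], dtype=float)
        n, L = geno.shape
        for l in range(L):
            p = geno[:, l] / 2.0
            pbar = p.mean()
            dev = p - pbar
            ordered_sum = sum(dev[i] * dev[j] for i in range(n) for j in range(n)
                              if i != j)
            assert ordered_sum == pytest.approx(-np.sum(dev ** 2), abs=1e-14)


class TestDegenerateInputs:
    def test_monomorphic_loiselle_errors(self):
        with pytest.raises(ValueError, match="no polymorphism"):
            loiselle_kinship(make_table([[0, 0], [0, 0], [0, 0]]))

    def test_all_homozygous_rousset_errors(self):
        with pytest.raises(ValueError, match="homozygous"):
            rousset_a(make_table([[0, 2], [2, 0], [0, 0]]))

    def test_duplicate_homozygotes_have_minimal_a(self):
        geno = [[0, 2, 0], [0, 2, 0], [1, 1, 2], [2, 0, 1]]
        table = rousset_a(make_table(geno))
        vals = table.values()
        pair = [k for k in range(table.n_pairs)
                if {table.i[k], table.j[k]} == {"i0", "i1"}][0]
        assert vals[pair] == vals.min()


class TestInvariances:
    def _random_table(self, seed, n=8, L=20):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, (n, L)).astype(np.int8)
        g[rng.random((n, L)) < 0.1] = MISSING
        return g

    @pytest.mark.parametrize("metric", [loiselle_kinship, rousset_a])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_locus_order_and_allele_flip_invariance(self, metric, seed):
        g = self._random_table(seed)
        t = make_table(g)
        base = metric(t).values()
        perm = np.random.default_rng(seed + 10).permutation(g.shape[1])
        np.testing.assert_allclose(metric(t.take_loci(perm)).values(), base,
                                   atol=1e-12)
        flipped = np.where(g == MISSING, MISSING, 2 - g).astype(np.int8)
        np.testing.assert_allclose(metric(make_table(flipped)).values(), base,
                                   atol=1e-12)

    def test_single_polymorphic_locus_equals_single_locus_value(self):
        g = np.zeros((5, 4), dtype=np.int8)
        g[:, 2] = [0, 1, 2, 1, 0]  # only locus 2 polymorphic
        multi = loiselle_kinship(make_table(g)).values()
        single = loiselle_kinship(make_table(g[:, [2]])).values()
        np.testing.assert_allclose(multi, single, atol=1e-12)

    def test_panmictic_mean_a_near_zero(self):
        rng = np.random.default_rng(5)
        p = rng.beta(1, 1, 300)
        g = rng.binomial(2, p, (100, 300)).astype(np.int8)
        vals = rousset_a(make_table(g)).values()
        assert abs(vals.mean()) < 0.01


class TestFirstDistanceClass:
    def test_constant_metric(self):
        from ibdispersal.metrics import PairMetricTable

        t = PairMetricTable("loiselle_F", np.array(["a", "b", "c"]),
                            np.array(["b", "c", "a"]), np.array([1.0, 2.0, 3.0]),
                            np.full((3, 1), 0.07), np.ones((3, 1)))
        assert mean_kinship_first_class(t, 2.5) == pytest.approx(0.07)
        with pytest.raises(ValueError, match="radius"):
            mean_kinship_first_class(t, 0.5)


class TestPopulationSummaries:
    def test_fis_extremes(self):
        groups = {f"i{k}": "G" for k in range(4)}
        all_hom = make_table([[0, 2], [2, 0], [0, 0], [2, 2]])
        assert fis(all_hom, groups)["G"] == pytest.approx(1.0)
        all_het = make_table([[1, 1], [1, 1], [1, 1], [1, 1]])
        assert fis(all_het, groups)["G"] == pytest.approx(-1.0)

    def test_fis_hardy_weinberg_near_zero(self):
        rng = np.random.default_rng(8)
        p = rng.beta(1, 1, 500)
        g = rng.binomial(2, p, (200, 500)).astype(np.int8)
        out = fis(make_table(g), {f"i{k}": "G" for k in range(200)})
        assert abs(out["G"]) < 0.05

    def test_fis_monomorphic_nan(self):
        out = fis(make_table([[0, 0], [0, 0]]), {"i0": "G", "i1": "G"})
        assert np.isnan(out["G"])

    def test_fst_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(9)
        p = rng.beta(1, 1, 400)
        g = rng.binomial(2, p, (200, 400)).astype(np.int8)
        groups = {f"i{k}": ("A" if k < 100 else "B") for k in range(200)}
        theta = fst_wc(make_table(g), groups)["theta"].iloc[0]
        assert abs(theta) < 0.01

    def test_fst_fixed_differences_one(self):
        g = np.array([[0, 0], [0, 0], [0, 0], [2, 2], [2, 2], [2, 2]],
                     dtype=np.int8)
        groups = {f"i{k}": ("A" if k < 3 else "B") for k in range(6)}
        theta = fst_wc(make_table(g), groups)["theta"].iloc[0]
        assert theta == pytest.approx(1.0)

    def test_fst_island_model_oracle(self):
        """Forward island-model simulation (common migrant pool):
        equilibrium theta ~ 1/(1 + 4Nm)."""
        rng = np.random.default_rng(12)
        d, N, m, L, G = 4, 100, 0.025, 300, 200
        freqs = np.full((d, L), 0.5)
        for _ in range(G):
            pbar = freqs.mean(axis=0)
            post = (1 - m) * freqs + m * pbar
            freqs = rng.binomial(2 * N, post) / (2 * N)
        geno = np.vstack([
            rng.binomial(2, freqs[k], (30, L)) for k in range(d)
        ]).astype(np.int8)
        groups = {f"i{k}": f"D{k // 30}" for k in range(30 * d)}
        theta = fst_wc(make_table(geno), groups)["theta"].mean()
        expected = 1.0 / (1.0 + 4 * N * m)
        assert theta == pytest.approx(expected, rel=0.3)
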