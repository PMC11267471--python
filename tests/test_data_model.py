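"""Readers, filtering, coordinate handling and pairwise distances."""

import numpy as np
import pandas as pd
import pytest

from ibdispersal.data_model import (
    MISSING,
    ColonyMap,
    FilterConfig,
    GenotypeTable,
    ParseError,
    filter_genotypes,
    flatten_plots,
    pairwise_distance_2d,
    read_colony_map,
    read_genotypes,
    thin_one_snp_per_contig,
    transform_coordinates,
    write_genotype_tsv,
    write_vcf,
)

from .conftest import make_colony_map, make_table

VCF_SMALL = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=ctg1>
##contig=<ID=ctg2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampA\tsampB
ctg1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1
ctg1\t20\t.\tC\tG\t.\tPASS\t.\tGT\t1/1\t./.
ctg2\t5\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1
"""

VCF_TRIALLELIC = VCF_SMALL + "ctg2\t9\t.\tG\tA,C\t.\tPASS\t.\tGT\t0/1\t1/2\n"


class TestReaders:
    def test_vcf_parse(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text(VCF_SMALL)
        t = read_genotypes(str(p))
        assert t.individual_ids == ["sampA", "sampB"]
        assert t.contig_ids == ["ctg1", "ctg1", "ctg2"]
        expected = np.array([[0, 2, 1], [1, MISSING, 2]], dtype=np.int8)
        np.testing.assert_array_equal(t.genotypes, expected)

    def test_vcf_multiallelic_rejected(self, tmp_path):
        p = tmp_path / "x.vcf"
        p.write_text(VCF_TRIALLELIC)
        with pytest.raises(ParseError, match="ctg2:9"):
            read_genotypes(str(p))

    def test_tsv_round_trip(self, tmp_path):
        t = make_table([[0, 1, 2], [2, MISSING, 0]])
        path = tmp_path / "g.tsv"
        write_genotype_tsv(t, str(path))
        back = read_genotypes(str(path))
        np.testing.assert_array_equal(back.genotypes, t.genotypes)
        assert back.individual_ids == t.individual_ids
        assert back.contig_ids == t.contig_ids

    def test_vcf_round_trip(self, tmp_path):
        t = make_table([[0, 1, 2], [2, MISSING, 0]])
        path = tmp_path / "g.vcf"
        write_vcf(t, str(path))
        back = read_genotypes(str(path))
        np.testing.assert_array_equal(back.genotypes, t.genotypes)

    def test_colony_map_errors(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("id\tlocation\tplot\tx\ty\tz\na\tL1\tP1\t0\t0\t5\nb\tL1\tP1\t1\t1\t5\n")
        cmap = read_colony_map(str(p))
        assert len(cmap.table) == 2
        p.write_text("id\tlocation\tplot\tx\ty\tz\na\tL1\tP1\t0\t0\t5\na\tL1\tP1\t1\t1\t5\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_colony_map(str(p))
        p.write_text("id\tlocation\tplot\tx\ty\na\tL1\tP1\t0\t0\n")
        with pytest.raises(ParseError, match="missing column"):
            read_colony_map(str(p))

    def test_colony_map_warns_on_missing_coordinates(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("id\tlocation\tplot\tx\ty\tz\na\tL1\tP1\t0\t0\t5\n")
        with pytest.warns(UserWarning, match="lack coordinates"):
            read_colony_map(str(p), genotyped_ids=["a", "b"])


class TestTransforms:
    def _cmap(self):
        return make_colony_map({"a": (0, 0), "b": (3, 4), "c": (1, 1)})

    def test_identity(self):
        c = self._cmap()
        out = transform_coordinates(c, {"P1": {}})
        pd.testing.assert_frame_equal(out.table, c.table)

    def test_scale_doubles_distances(self):
        c = self._cmap()
        out = transform_coordinates(c, {"P1": {"scale": 2.0}})
        d0 = pairwise_distance_2d(c)
        d1 = pairwise_distance_2d(out)
        np.testing.assert_allclose(d1["d"], 2.0 * d0["d"])

    def test_translation_is_isometry(self):
        c = self._cmap()
        out = transform_coordinates(c, {"P1": {"translate": [10, -3, 2]}})
        np.testing.assert_allclose(
            pairwise_distance_2d(out)["d"], pairwise_distance_2d(c)["d"]
        )

    def test_missing_transform_errors(self):
        with pytest.raises(ValueError, match="no transform"):
            transform_coordinates(self._cmap(), {"other": {}})

    def test_flatten_removes_normal_component(self):
        # tilted plane plus off-plane noise: after flattening the cloud is
        # exactly planar and flattening is idempotent
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 10, (20, 2))
        z = 5.0 + 0.5 * xy[:, 0] + rng.normal(0, 0.1, 20)
        cmap = make_colony_map({f"c{k}": (xy[k, 0], xy[k, 1], z[k])
                                for k in range(20)})
        flat = flatten_plots(cmap)
        coords = flat.table[["x", "y", "z"]].to_numpy()
        s = np.linalg.svd(coords - coords.mean(0), compute_uv=False)
        assert s[2] < 1e-9  # rank 2: no residual normal component
        again = flatten_plots(flat)
        np.testing.assert_allclose(
            again.table[["x", "y", "z"]].to_numpy(), coords, atol=1e-9
        )


class TestPairwiseDistance:
    def test_three_four_five(self):
        cmap = make_colony_map({"a": (0, 0), "b": (3, 4)})
        d = pairwise_distance_2d(cmap)
        assert d["d"].iloc[0] == pytest.approx(5.0)

    def test_cross_location_excluded_cross_plot_included(self):
        rows = pd.DataFrame([
            {"id": "a", "location": "L1", "plot": "P1", "x": 0, "y": 0, "z": 0},
            {"id": "b", "location": "L1", "plot": "P2", "x": 1, "y": 0, "z": 0},
            {"id": "c", "location": "L2", "plot": "P3", "x": 2, "y": 0, "z": 0},
        ])
        d = pairwise_distance_2d(ColonyMap(rows))
        got = {frozenset(p) for p in zip(d["i"], d["j"])}
        assert got == {frozenset({"a", "b"})}

    def test_coincident_floored(self):
        cmap = make_colony_map({"a": (1, 1), "b": (1, 1)})
        with pytest.warns(UserWarning, match="floored"):
            d = pairwise_distance_2d(cmap)
        assert d["d"].iloc[0] == pytest.approx(0.01)

    def test_plot_geometry_bound(self, sampled_sim):
        sub = sampled_sim.colony_map.table
        one_plot = ColonyMap(sub[sub["plot"] == "P1"].reset_index(drop=True))
        d = pairwise_distance_2d(one_plot)
        assert (d["d"] <= np.hypot(25, 4) + 1e-9).all()

    def test_symmetry_and_triangle_inequality(self, sampled_sim):
        cmap = sampled_sim.colony_map
        d = pairwise_distance_2d(cmap)
        lut = {}
        for r in d.itertuples():
            lut[(r.i, r.j)] = r.d
            lut[(r.j, r.i)] = r.d
        ids = cmap.ids
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b, c = rng.choice(ids, 3, replace=False)
            if (a, b) in lut and (b, c) in lut and (a, c) in lut:
                assert lut[(a, c)] <= lut[(a, b)] + lut[(b, c)] + 1e-9


class TestFiltering:
    def test_individual_missingness_threshold(self):
        g = [[0, 1, 2, 0, 1], [MISSING, MISSING, MISSING, 0, 1]]  # 60% missing
        t = make_table(g)
        out, report = filter_genotypes(
            t, FilterConfig(min_allele_count=1, max_snp_missing=1.0)
        )
        assert out.individual_ids == ["i0"]
        assert report["individuals_removed_missing"] == 1

    def test_mac_threshold(self):
        # locus 0: minor-allele count 2 -> removed at MAC 3; locus 1: MAC 3 kept
        g = [[1, 1], [1, 1], [0, 1], [0, 0], [0, 0], [0, 0]]
        t = make_table(g)
        out, report = filter_genotypes(t, FilterConfig())
        assert out.locus_ids == [t.locus_ids[1]]
        assert report["loci_removed_mac"] == 1

    def test_clean_table_unchanged(self):
        g = [[0, 2], [1, 1], [2, 0], [1, 1], [0, 2], [2, 0]]
        t = make_table(g)
        out, _ = filter_genotypes(t, FilterConfig())
        np.testing.assert_array_equal(out.genotypes, t.genotypes)

    def test_all_filtered_errors(self):
        t = make_table([[0, 0], [0, 0], [0, 0]])  # monomorphic, MAC 0
        with pytest.raises(ValueError, match="all data filtered"):
            filter_genotypes(t, FilterConfig())

    def test_idempotent_on_realistic_data(self, small_sim):
        from ibdispersal.simulate import add_genotyping_noise

        noisy = add_genotyping_noise(small_sim, 0.005, 0.1, seed=5)
        once, _ = filter_genotypes(noisy.genotypes, FilterConfig())
        twice, rep2 = filter_genotypes(once, FilterConfig())
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)
        assert rep2["individuals_removed_missing"] == 0


class TestThinning:
    def test_one_per_contig(self):
        g = np.tile([0, 1, 2], (4, 5)).astype(np.int8)
        contigs = [f"c{l % 3}" for l in range(15)]
        t = make_table(g, contig_per_locus=contigs)
        out = thin_one_snp_per_contig(t, seed=1)
        assert out.n_loci == 3
        assert sorted(set(out.contig_ids)) == ["c0", "c1", "c2"]

    def test_deterministic(self):
        g = np.zeros((3, 12), dtype=np.int8)
        g[0] = 1
        contigs = [f"c{l // 4}" for l in range(12)]
        t = make_table(g, contig_per_locus=contigs)
        a = thin_one_snp_per_contig(t, seed=42)
        b = thin_one_snp_per_contig(t, seed=42)
        assert a.locus_ids == b.locus_ids

    def test_singleton_contig_forced(self):
        t = make_table([[0, 1], [1, 0], [2, 1]], contig_per_locus=["c0", "c1"])
        out = thin_one_snp_per_contig(t, seed=0)
        assert set(out.contig_ids) == {"c0", "c1"}
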