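"""Generator contracts: determinism, count bounds, convergence to the
configured global level, planted effect sizes, mixtures, fixtures."""

import numpy as np
import pandas as pd
import pytest

import cfmethyl as cm
from cfmethyl.intervals import merge_intervals, total_length


@pytest.fixture(scope="module")
def small_spec():
    return cm.GenomeSpec.random({"chr1": 200_000, "chr2": 100_000}, 100, seed=11)


class TestSimulateMethylome:
    def test_same_seed_is_bit_identical(self, small_spec):
        a, _ = cm.simulate_methylome(small_spec, (3, 3), seed=5)
        b, _ = cm.simulate_methylome(small_spec, (3, 3), seed=5)
        assert np.array_equal(a.meth, b.meth) and np.array_equal(a.total, b.total)
        c, _ = cm.simulate_methylome(small_spec, (3, 3), seed=6)
        assert not np.array_equal(a.meth, c.meth)

    def test_counts_bounded_by_coverage(self, small_spec):
        counts, _ = cm.simulate_methylome(small_spec, (4, 4), dispersion=0.0,
                                          coverage_mean=3.0, seed=7)
        assert counts.meth.min() >= 0
        assert np.all(counts.meth <= counts.total)
        assert counts.total.min() >= 1

    def test_global_level_converges_to_baseline(self):
        # 50k sites: the pooled weighted methylation tracks the configured
        # 83% global level within 0.01
        spec = cm.GenomeSpec.random({"chr1": 5_000_000}, 100, seed=21)
        counts, _ = cm.simulate_methylome(spec, (2, 2), baseline_mean=0.83,
                                          coverage_mean=10.0, seed=22)
        assert counts.n_sites > 45_000
        assert abs(cm.weighted_global_methylation(counts) - 0.83) < 0.01

    def test_planted_shift_is_expressed_in_the_counts(self, small_spec):
        region = cm.PlantedDMR("chr1", 50_000, 52_000, -0.3)
        counts, _ = cm.simulate_methylome(small_spec, (5, 5), [region],
                                          coverage_mean=30.0, seed=23)
        mask = (counts.chrom.astype(str) == "chr1") & (counts.pos >= 50_000) & (counts.pos < 52_000)
        g1 = cm.weighted_global_methylation(counts, group="group1", site_mask=mask)
        g2 = cm.weighted_global_methylation(counts, group="group2", site_mask=mask)
        assert (g2 - g1) == pytest.approx(-0.3, abs=0.05)

    def test_planted_region_without_cpg_rejected(self, small_spec):
        pos = small_spec.cpg_pos["chr1"]
        gap_at = int(pos[10]) + 1  # between two CpGs
        with pytest.raises(ValueError, match="no CpG"):
            cm.simulate_methylome(small_spec, (2, 2),
                                  [cm.PlantedDMR("chr1", gap_at, gap_at + 1, 0.2)], seed=1)

    def test_overlapping_planted_regions_rejected(self, small_spec):
        regions = [cm.PlantedDMR("chr1", 10_000, 12_000, 0.2),
                   cm.PlantedDMR("chr1", 11_000, 13_000, 0.2)]
        with pytest.raises(ValueError, match="overlap"):
            cm.simulate_methylome(small_spec, (2, 2), regions, seed=1)


class TestSimulateMixture:
    def test_pure_tissue_reproduces_the_panel_column(self, panel):
        e = np.zeros(14)
        e[4] = 1.0
        obs = cm.simulate_mixture(panel, e)
        np.testing.assert_allclose(obs, panel.fractions.iloc[:, 4].to_numpy())

    def test_even_mix_is_the_elementwise_midpoint(self, panel):
        p = np.zeros(14)
        p[[0, 1]] = 0.5
        obs = cm.simulate_mixture(panel, p)
        mid = 0.5 * (panel.fractions.iloc[:, 0] + panel.fractions.iloc[:, 1])
        np.testing.assert_allclose(obs, mid.to_numpy())

    def test_noise_is_clipped_and_reproducible(self, panel):
        a = cm.simulate_mixture(panel, np.full(14, 1 / 14), noise_sd=0.05, seed=3)
        b = cm.simulate_mixture(panel, np.full(14, 1 / 14), noise_sd=0.05, seed=3)
        assert np.array_equal(a, b)
        assert a.min() >= 0 and a.max() <= 1

    def test_wrong_length_rejected(self, panel):
        with pytest.raises(ValueError, match="tissues"):
            cm.simulate_mixture(panel, np.full(5, 0.2))


class TestExternalSummary:
    def _dml(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(n) * 100,
             "diff": rng.normal(0, 0.1, n)}
        )

    def test_perfect_concordance_gives_infinite_odds_ratio(self):
        dml = self._dml(500)
        ext = cm.simulate_external_summary(dml, concordant_fraction=1.0, seed=1)
        signs = np.where(dml["diff"] >= 0, 1, -1)
        _, fisher = cm.direction_concordance(signs, ext["direction"].to_numpy())
        assert fisher.odds_ratio == np.inf

    def test_random_directions_give_null_odds_ratio(self):
        dml = self._dml(10_000, seed=2)
        ext = cm.simulate_external_summary(dml, concordant_fraction=0.5, seed=3)
        signs = np.where(dml["diff"] >= 0, 1, -1)
        _, fisher = cm.direction_concordance(signs, ext["direction"].to_numpy())
        assert fisher.odds_ratio == pytest.approx(1.0, abs=0.1)

    def test_seeded_determinism_and_empty_input(self):
        dml = self._dml(100)
        a = cm.simulate_external_summary(dml, 0.7, 0.2, seed=9)
        b = cm.simulate_external_summary(dml, 0.7, 0.2, seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert len(cm.simulate_external_summary(dml.iloc[:0], 0.7, 0.2, seed=9)) == 0


class TestAnnotationFixture:
    def test_each_layer_partitions_the_genome(self, fixture_annotation):
        spec, ann, _ = fixture_annotation
        from cfmethyl.io import CGI_LAYER, GENE_LAYER

        for layer in (GENE_LAYER, CGI_LAYER):
            for c, size in spec.chrom_sizes.items():
                ivs = []
                covered = 0
                for f in layer:
                    iv = ann.feature_intervals(f).get(c)
                    if iv is not None and len(iv):
                        ivs.extend(map(tuple, iv))
                        covered += total_length(iv)
                # disjoint (sum of parts == length of union) and exhaustive
                assert covered == total_length(merge_intervals(ivs)) == size

    def test_minus_strand_promoter_lies_downstream_of_gene_end(self, fixture_annotation):
        _, ann, genes = fixture_annotation
        minus = genes[genes["strand"] == "-"].iloc[0]
        proms = ann.df[(ann.df["feature"] == "promoter") & (ann.df["chrom"] == minus["chrom"])]
        hit = proms[(proms["start"] >= minus["end"]) & (proms["start"] < minus["end"] + 10)]
        assert len(hit) >= 1  # promoter starts at the minus-strand TSS (= gene end)

    def test_seeded_determinism(self):
        spec = cm.GenomeSpec.random({"chr1": 500_000}, 150, seed=31)
        a, ga = cm.make_annotation_fixture(spec, 20, seed=32)
        b, gb = cm.make_annotation_fixture(spec, 20, seed=32)
        pd.testing.assert_frame_equal(a.df, b.df)
        pd.testing.assert_frame_equal(ga, gb)

    def test_too_many_genes_rejected(self):
        spec = cm.GenomeSpec.random({"chr1": 100_000}, 150, seed=33)
        with pytest.raises(ValueError, match="without overlap"):
            cm.make_annotation_fixture(spec, 50, seed=34)
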