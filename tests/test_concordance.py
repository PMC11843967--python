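"""Global methylation summaries and exact Fisher statistics, including a
brute-force hypergeometric enumeration oracle and the closed-form
conditional-MLE check."""

from math import comb

import numpy as np
import pandas as pd
import pytest

import cfmethyl as cm
from cfmethyl.concordance import ContingencyTable2x2


class TestWeightedGlobalMethylation:
    def make(self):
        return cm.CpGCountMatrix(
            np.array(["chr1", "chr1"], dtype=object), np.array([10, 20]),
            np.array([[3], [1]]), np.array([[4], [4]]), ["s"])

    def test_pooled_fraction(self):
        assert cm.weighted_global_methylation(self.make()) == pytest.approx(0.5)

    def test_equal_coverage_equals_plain_mean(self):
        counts = self.make()
        fracs = counts.meth[:, 0] / counts.total[:, 0]
        assert cm.weighted_global_methylation(counts) == pytest.approx(fracs.mean())

    def test_result_bounded_by_site_fractions(self):
        rng = np.random.default_rng(3)
        total = rng.integers(1, 50, size=(30, 2))
        meth = rng.binomial(total, 0.6)
        counts = cm.CpGCountMatrix(
            np.array(["chr1"] * 30, dtype=object), np.arange(30) * 10,
            meth, total, ["a", "b"])
        g = cm.weighted_global_methylation(counts)
        fr = meth.sum(1) / total.sum(1)
        assert fr.min() <= g <= fr.max()

    def test_zero_coverage_errors(self):
        counts = cm.CpGCountMatrix(
            np.array(["chr1"], dtype=object), np.array([1]),
            np.array([[0]]), np.array([[0]]), ["s"])
        with pytest.raises(ValueError, match="coverage"):
            cm.weighted_global_methylation(counts)


def oracle_two_sided(a, b, c, d, tie_tol=1.0 + 1e-7):
    """Exact integer-arithmetic enumeration of the two-sided p."""
    n, n1, m1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, n1 + m1 - n), min(n1, m1)
    ws = [comb(m1, k) * comb(n - m1, n1 - k) for k in range(lo, hi + 1)]
    wa = ws[a - lo]
    thr = wa * tie_tol
    return min(1.0, sum(w for w in ws if w <= thr) / sum(ws))


class TestFisherExact:
    def test_symmetric_table_is_null(self):
        r = cm.fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert r.odds_ratio == pytest.approx(1.0, abs=1e-9)
        assert r.pvalue == pytest.approx(1.0)

    def test_conditional_mle_closed_form(self):
        # E_psi[a] = 1 for margins of (1,1;3,2) solves 6 psi^2 = 3
        r = cm.fisher_exact_2x2(ContingencyTable2x2(1, 1, 3, 2))
        assert r.odds_ratio == pytest.approx(np.sqrt(0.5), abs=1e-9)
        assert round(r.odds_ratio, 2) == 0.71
        assert r.pvalue == pytest.approx(1.0)

    def test_large_direction_concordance_table(self):
        r = cm.fisher_exact_2x2(ContingencyTable2x2(4299, 3020, 3441, 4226))
        assert round(r.odds_ratio, 2) == 1.75
        assert r.pvalue < 2.2e-16

    def test_matches_enumeration_oracle_on_small_tables(self):
        for n in range(1, 13):
            for n1 in range(n + 1):
                for m1 in range(n + 1):
                    lo, hi = max(0, n1 + m1 - n), min(n1, m1)
                    for a in range(lo, hi + 1):
                        cells = (a, n1 - a, m1 - a, n - n1 - m1 + a)
                        got = cm.fisher_exact_2x2(ContingencyTable2x2(*cells)).pvalue
                        want = oracle_two_sided(*cells)
                        assert got == pytest.approx(want, rel=1e-9, abs=1e-300), cells

    def test_odds_ratio_symmetries(self):
        r = cm.fisher_exact_2x2(ContingencyTable2x2(8, 3, 2, 9))
        both = cm.fisher_exact_2x2(ContingencyTable2x2(9, 2, 3, 8))
        row = cm.fisher_exact_2x2(ContingencyTable2x2(2, 9, 8, 3))
        assert both.odds_ratio == pytest.approx(r.odds_ratio, rel=1e-8)
        assert row.odds_ratio == pytest.approx(1.0 / r.odds_ratio, rel=1e-8)
        assert both.pvalue == pytest.approx(r.pvalue, rel=1e-12)

    def test_boundary_counts_give_sentinels(self):
        assert cm.fisher_exact_2x2(ContingencyTable2x2(5, 0, 1, 4)).odds_ratio == np.inf
        assert cm.fisher_exact_2x2(ContingencyTable2x2(0, 5, 4, 1)).odds_ratio == 0.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)


class TestOverlapTable:
    def test_enumerated_example(self):
        t = cm.build_overlap_table({1, 2, 3, 4}, {3, 4, 5, 6}, set(range(1, 11)))
        assert (t.a, t.b, t.c, t.d) == (2, 2, 2, 4)

    def test_identical_sets_have_empty_off_diagonals(self):
        t = cm.build_overlap_table({1, 2}, {1, 2}, set(range(8)))
        assert t.b == t.c == 0

    def test_disjoint_sets_share_nothing(self):
        t = cm.build_overlap_table({1}, {2}, set(range(8)))
        assert t.a == 0

    def test_element_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            cm.build_overlap_table({99}, {1}, {1, 2})


class TestDirectionConcordance:
    def test_published_style_counts_reproduce(self):
        s1 = np.concatenate([-np.ones(4299 + 3020), np.ones(3441 + 4226)])
        s2 = np.concatenate([-np.ones(4299), np.ones(3020), -np.ones(3441), np.ones(4226)])
        table, fisher = cm.direction_concordance(s1, s2)
        assert (table.a, table.b, table.c, table.d) == (4299, 3020, 3441, 4226)
        assert round(fisher.odds_ratio, 2) == 1.75

    def test_all_concordant_is_infinite(self):
        _, fisher = cm.direction_concordance([-1, -1, 1, 1], [-1, -1, 1, 1])
        assert fisher.odds_ratio == np.inf

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cm.direction_concordance([])


class TestCpgRegionEnrichment:
    def universe(self, n=50_000, seed=61):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(5_000_000, size=n, replace=False))
        return pd.DataFrame({"chrom": "chr1", "pos": pos}), rng

    def test_unplanted_sets_are_unenriched(self):
        uni, rng = self.universe()
        regions = pd.DataFrame({"chrom": "chr1", "start": np.arange(0, 5_000_000, 100_000),
                                "end": np.arange(0, 5_000_000, 100_000) + 10_000})
        pick = rng.random(len(uni)) < 0.01
        cpgs = list(zip(uni["chrom"][pick], uni["pos"][pick]))
        _, fisher = cm.cpg_region_enrichment(cpgs, regions, uni)
        assert fisher.odds_ratio == pytest.approx(1.0, abs=0.15)

    def test_planted_propensity_is_recovered(self):
        uni, rng = self.universe(seed=62)
        regions = pd.DataFrame({"chrom": "chr1", "start": np.arange(0, 5_000_000, 100_000),
                                "end": np.arange(0, 5_000_000, 100_000) + 10_000})
        inside = np.zeros(len(uni), dtype=bool)
        for s in range(0, 5_000_000, 100_000):
            inside |= (uni["pos"] >= s) & (uni["pos"] < s + 10_000)
        # odds-based planting so the odds ratio, not the rate ratio, is 5
        base = 0.01
        prob_odds = np.where(inside, 5 * base / (1 - base + 5 * base), base)
        pick = rng.random(len(uni)) < prob_odds
        cpgs = list(zip(uni["chrom"][pick], uni["pos"][pick]))
        _, fisher = cm.cpg_region_enrichment(cpgs, regions, uni)
        assert fisher.odds_ratio == pytest.approx(5.0, abs=0.5)

    def test_regions_covering_everything_degenerate(self):
        uni = pd.DataFrame({"chrom": "chr1", "pos": np.arange(100)})
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        table, fisher = cm.cpg_region_enrichment([("chr1", 1)], regions, uni)
        assert table.b == 0 and fisher.pvalue == 1.0
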