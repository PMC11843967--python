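"""Differential methylation testing: smoothing arithmetic, dispersion
shrinkage against a brute-force grid oracle, the Wald statistic against
hand-computed values, and calibration-style invariants."""

import numpy as np
import pytest
from scipy import stats

import cfmethyl as cm
from cfmethyl.dml import LOG_PHI_BOUNDS


def matrix(pos, meth, total, n_group1, chrom="chr1"):
    meth = np.atleast_2d(np.asarray(meth))
    total = np.atleast_2d(np.asarray(total))
    n_samples = meth.shape[1]
    samples = [f"s{i}" for i in range(n_samples)]
    groups = {s: ("g1" if i < n_group1 else "g2") for i, s in enumerate(samples)}
    return cm.CpGCountMatrix(
        np.array([chrom] * len(pos), dtype=object), np.asarray(pos),
        meth, total, samples, groups,
    )


class TestSmoothMeans:
    def test_window_zero_is_the_raw_site_fraction(self):
        counts = matrix([100], [[3, 2]], [[4, 4]], n_group1=1)
        sm = cm.smooth_means(counts, window_bp=0)
        assert sm.mu[0, 0] == 0.75
        assert sm.mu[0, 1] == 0.5

    def test_equal_coverage_gives_the_plain_average(self):
        # three sites with N=10 and fractions 0.2/0.4/0.6 inside one window
        counts = matrix([100, 120, 140],
                        [[2, 2], [4, 4], [6, 6]], [[10, 10]] * 3, n_group1=1)
        sm = cm.smooth_means(counts, window_bp=500)
        assert sm.mu[1, 0] == pytest.approx(0.4)

    def test_unequal_coverage_weights_by_reads(self):
        # N=(10,30), fractions (0.2, 0.6) -> (2+18)/40 = 0.5
        counts = matrix([100, 150], [[2, 2], [18, 18]], [[10, 10], [30, 30]], n_group1=1)
        sm = cm.smooth_means(counts, window_bp=500)
        assert sm.mu[0, 0] == pytest.approx(0.5)

    def test_uncovered_group_is_flagged_undefined(self):
        counts = matrix([100], [[3, 0]], [[4, 0]], n_group1=1)
        sm = cm.smooth_means(counts, window_bp=0)
        assert np.isnan(sm.mu[0, 1])


def _prior_from_moments(counts, sm):
    """Independent re-derivation of the log-MoM prior (m0, s0)."""
    mu = np.clip(np.repeat(sm.mu, [counts.group_columns("g1").size,
                                   counts.group_columns("g2").size], axis=1), 1e-4, 1 - 1e-4)
    N = counts.total.astype(float)
    M = counts.meth.astype(float)
    usable = N > 0
    p = np.where(usable, M / np.maximum(N, 1), np.nan)
    v = mu * (1 - mu)
    num = np.nansum(np.where(usable, (p - mu) ** 2 - v / np.maximum(N, 1), np.nan), axis=1)
    den = np.nansum(np.where(usable, v * (1 - 1 / np.maximum(N, 1)), np.nan), axis=1)
    mom = num / den
    good = (usable.sum(axis=1) >= 2) & (mom > 0)
    logs = np.log(np.clip(mom[good], np.exp(LOG_PHI_BOUNDS[0]), np.exp(LOG_PHI_BOUNDS[1])))
    return float(np.mean(logs)), max(float(np.std(logs)), 0.5)


@pytest.fixture(scope="module")
def fixture20():
    rng = np.random.default_rng(77)
    n_sites, n_samples = 20, 6
    pos = np.arange(n_sites) * 10_000  # isolated sites: window = site
    total = rng.integers(5, 40, size=(n_sites, n_samples))
    p = rng.beta(8, 2, size=(n_sites, 1))
    meth = rng.binomial(total, np.clip(p + rng.normal(0, 0.08, total.shape), 0.01, 0.99))
    return matrix(pos, meth, total, n_group1=3)


class TestDispersion:

    def test_infinite_prior_weight_collapses_to_the_prior_mean(self, fixture20):
        sm = cm.smooth_means(fixture20, 0)
        phi = cm.estimate_dispersion(fixture20, sm, prior_weight=np.inf)
        assert np.allclose(phi, phi[0])

    def test_golden_section_matches_brute_force_grid(self, fixture20):
        """10^4-point grid oracle of the penalized likelihood."""
        sm = cm.smooth_means(fixture20, 0)
        phi = cm.estimate_dispersion(fixture20, sm)
        m0, s0 = _prior_from_moments(fixture20, sm)
        # sanity: the prior the implementation used is the same one
        assert np.exp(m0) == pytest.approx(
            cm.estimate_dispersion(fixture20, sm, prior_weight=np.inf)[0], rel=1e-9)
        grid = np.linspace(*LOG_PHI_BOUNDS, 10_000)
        mu = np.clip(sm.mu, 1e-4, 1 - 1e-4)
        n1 = fixture20.group_columns("g1").size
        for i in range(20):
            obj = np.zeros_like(grid)
            for j in range(fixture20.n_samples):
                g = 0 if j < n1 else 1
                a = mu[i, g] * (1 - np.exp(grid)) / np.exp(grid)
                b = (1 - mu[i, g]) * (1 - np.exp(grid)) / np.exp(grid)
                obj += stats.betabinom.logpmf(
                    fixture20.meth[i, j], fixture20.total[i, j], a, b)
            obj -= (grid - m0) ** 2 / (2 * s0**2)
            best = grid[np.argmax(obj)]
            step = grid[1] - grid[0]
            assert abs(np.log(phi[i]) - best) <= step + 1e-4

    def test_zero_observed_overdispersion_shrinks_at_or_below_prior(self):
        rng = np.random.default_rng(5)
        pos = np.arange(30) * 10_000
        total = np.full((30, 6), 20)
        meth = rng.binomial(total, 0.8)
        meth[0] = 16  # identical counts in every sample at site 0
        counts = matrix(pos, meth, total, n_group1=3)
        sm = cm.smooth_means(counts, 0)
        phi = cm.estimate_dispersion(counts, sm)
        prior = cm.estimate_dispersion(counts, sm, prior_weight=np.inf)[0]
        assert phi[0] <= prior * (1 + 1e-9)


class TestWaldTest:
    def test_identical_groups_give_zero_statistic(self):
        counts = matrix([100], [[5, 5]], [[10, 10]], n_group1=1)
        sm = cm.smooth_means(counts, 0)
        df = cm.dml_wald_test(counts, sm, np.zeros(1))
        assert df["diff"].iloc[0] == 0
        assert df["stat"].iloc[0] == 0
        assert df["pval"].iloc[0] == 1

    def test_hand_computed_single_site_example(self):
        # M=(8, 2), N=(10, 10), phi=0: Var = 0.8*0.2/10 + 0.2*0.8/10 = 0.032
        counts = matrix([100], [[8, 2]], [[10, 10]], n_group1=1)
        sm = cm.smooth_means(counts, 0)
        df = cm.dml_wald_test(counts, sm, np.zeros(1))
        assert df["se"].iloc[0] ** 2 == pytest.approx(0.032)
        assert df["stat"].iloc[0] == pytest.approx(3.3541, abs=1e-4)
        assert df["pval"].iloc[0] == pytest.approx(7.95e-4, rel=1e-2)

    def test_statistic_shrinks_as_dispersion_grows(self):
        counts = matrix([100], [[8, 2]], [[10, 10]], n_group1=1)
        sm = cm.smooth_means(counts, 0)
        w0 = abs(cm.dml_wald_test(counts, sm, np.array([0.0]))["stat"].iloc[0])
        w1 = abs(cm.dml_wald_test(counts, sm, np.array([0.2]))["stat"].iloc[0])
        assert w1 < w0

    def test_group_role_swap_flips_sign_and_keeps_pvalue(self, null_dml_run):
        counts, dml = null_dml_run
        cols2 = counts.group_columns("group2")
        cols1 = counts.group_columns("group1")
        order = np.concatenate([cols2, cols1])
        counts2 = cm.CpGCountMatrix(
            counts.chrom, counts.pos, counts.meth[:, order], counts.total[:, order],
            [counts.samples[i] for i in order], counts.groups)
        dml2 = cm.test_dml(counts2)
        np.testing.assert_allclose(dml2["stat"], -dml["stat"], atol=1e-6)
        np.testing.assert_allclose(dml2["pval"], dml["pval"], atol=1e-6)

    def test_reduces_to_two_proportion_z_test(self):
        rng = np.random.default_rng(9)
        pos = np.arange(50) * 10_000
        total = rng.integers(5, 30, (50, 8))
        meth = rng.binomial(total, 0.7)
        counts = matrix(pos, meth, total, n_group1=4)
        sm = cm.smooth_means(counts, 0)
        df = cm.dml_wald_test(counts, sm, np.zeros(50))
        m1 = counts.meth[:, :4].sum(1); n1 = counts.total[:, :4].sum(1)
        m2 = counts.meth[:, 4:].sum(1); n2 = counts.total[:, 4:].sum(1)
        p1, p2 = m1 / n1, m2 / n2
        v1 = np.maximum(p1 * (1 - p1) / n1, 1e-8)
        v2 = np.maximum(p2 * (1 - p2) / n2, 1e-8)
        z = (p1 - p2) / np.sqrt(v1 + v2)
        np.testing.assert_allclose(df["stat"], z, atol=1e-9)

    def test_power_at_high_coverage(self):
        # planted |delta| = 0.25 at 30x: >= 90% of in-region sites significant
        spec = cm.GenomeSpec.random({"chr1": 200_000}, 30, seed=41)
        region = cm.PlantedDMR("chr1", 90_000, 92_000, -0.25)
        counts, _ = cm.simulate_methylome(spec, (5, 5), [region],
                                          coverage_mean=30.0, seed=42)
        dml = cm.test_dml(counts)
        inside = (dml["pos"] >= 90_000) & (dml["pos"] < 92_000)
        assert inside.sum() > 30
        assert (dml.loc[inside, "pval"] < 0.05).mean() >= 0.9


class TestMultipleTesting:
    @pytest.mark.parametrize(
        "p, q",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_benjamini_hochberg_by_hand(self, p, q):
        np.testing.assert_allclose(cm.adjust_bh(p), q)

    def test_empty_input(self):
        assert len(cm.adjust_bh([])) == 0

    def test_call_dml_filters_strictly(self, null_dml_run):
        _, dml = null_dml_run
        called = cm.call_dml(dml, 0.5)
        assert (called["fdr"] < 0.5).all()
        assert len(called) == (dml["fdr"] < 0.5).sum()
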