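"""Shared fixtures: seeded synthetic datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import cfmethyl as cm


@pytest.fixture(scope="session")
def null_dml_run():
    """Null two-group simulation (no planted effect): 20k CpGs, 5 vs 5
    samples, 10x coverage, phi = 0.05 — the calibration dataset."""
    spec = cm.GenomeSpec.random({"chr1": 2_000_000}, 100, seed=101)
    counts, _ = cm.simulate_methylome(
        spec, (5, 5), [], baseline_mean=0.83, dispersion=0.05,
        coverage_mean=10.0, seed=102,
    )
    dml = cm.test_dml(counts)
    return counts, dml


def plant_regions(n, chrom_sizes, length, delta, seed, margin=5000):
    """Place n non-overlapping planted DMRs uniformly on the genome."""
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    planted = []
    for i in range(n):
        c = chroms[i % len(chroms)]
        size = chrom_sizes[c]
        while True:
            s = int(rng.integers(margin, size - margin - length))
            if all(
                not (d.chrom == c and s < d.end + margin and d.start < s + length + margin)
                for d in planted
            ):
                break
        planted.append(cm.PlantedDMR(c, s, s + length, delta))
    return planted


@pytest.fixture(scope="session")
def recovery_run():
    """20 planted hypomethylated DMRs (|delta| = 0.25) on an island-like
    30 bp-spacing genome at 20x coverage — the region-recovery dataset."""
    sizes = {"chr1": 500_000, "chr2": 500_000}
    spec = cm.GenomeSpec.random(sizes, 30, seed=201)
    planted = plant_regions(20, sizes, length=1000, delta=-0.25, seed=202)
    counts, truth = cm.simulate_methylome(
        spec, (5, 5), planted, baseline_mean=0.83, dispersion=0.05,
        coverage_mean=20.0, seed=203,
    )
    dml = cm.test_dml(counts)
    dmrs = cm.call_dmr(dml)
    return counts, planted, dml, dmrs


@pytest.fixture(scope="session")
def fixture_annotation():
    """A 6 Mb two-chromosome genome with 300 gene models and CGI context."""
    spec = cm.GenomeSpec.random({"chr1": 3_000_000, "chr2": 3_000_000}, 200, seed=301)
    ann, genes = cm.make_annotation_fixture(spec, 300, seed=302)
    return spec, ann, genes


@pytest.fixture(scope="session")
def panel():
    """14-tissue synthetic reference panel, 280 Type I + 720 Type II."""
    return cm.synthetic_reference_panel(n_type1=280, n_type2=720, seed=401)


def overlaps(region_a, region_b) -> bool:
    """>= 1 bp overlap between (chrom, start, end) records."""
    return (
        region_a[0] == region_b[0]
        and region_a[1] < region_b[2]
        and region_b[1] < region_a[2]
    )


def dmr_match_rates(planted, dmrs: pd.DataFrame) -> tuple[float, float]:
    """(sensitivity, precision) under >= 1 bp overlap matching."""
    truths = [(d.chrom, d.start, d.end) for d in planted]
    calls = [(r.chrom, r.start, r.end) for r in dmrs.itertuples(index=False)]
    tp_t = sum(any(overlaps(t, c) for c in calls) for t in truths)
    tp_c = sum(any(overlaps(c, t) for t in truths) for c in calls)
    sens = tp_t / len(truths) if truths else float("nan")
    prec = tp_c / len(calls) if calls else float("nan")
    return sens, prec
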