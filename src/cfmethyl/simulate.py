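"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Real cfDNA WGBS data for this kind of study are not publicly deposited,
so every downstream stage is exercised on generated data with a known
ground truth: a desk-scale genome of CpG positions, two-group
beta-binomial methylation counts with spatially correlated means and
planted differential regions, convex tissue mixtures over a reference
panel, an external EWAS-like per-site summary with a controlled
concordance rate, and a gene/CpG-island annotation fixture.

The generator's defaults are the study conditions: global methylation
0.83 (the weighted mCG level the cfDNA cohorts average), dispersion
phi = 0.05, mean CpG spacing 100 bp, latent means constant within 1 kb
windows with between-window sd 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotationSet, CpGCountMatrix, ReferencePanel
from .intervals import complement_intervals, merge_intervals, subtract_intervals

__all__ = [
    "GenomeSpec",
    "PlantedDMR",
    "SyntheticTruth",
    "simulate_methylome",
    "simulate_mixture",
    "simulate_external_summary",
    "make_annotation_fixture",
    "synthetic_reference_panel",
]

DEFAULT_BASELINE = 0.83
DEFAULT_PHI = 0.05
DEFAULT_SPACING = 100
LATENT_WINDOW_BP = 1000
LATENT_SD = 0.15


@dataclass
class GenomeSpec:
    """Chromosome lengths plus sorted CpG positions — a desk-scale
    surrogate for reference-genome coordinates."""

    chrom_sizes: dict[str, int]
    cpg_pos: dict[str, np.ndarray]

    def __post_init__(self):
        for c, pos in self.cpg_pos.items():
            pos = np.asarray(pos, dtype=np.int64)
            if len(pos) and (np.any(np.diff(pos) <= 0)):
                raise ValueError(f"{c}: CpG positions must be strictly increasing")
            if len(pos) and (pos[0] < 0 or pos[-1] >= self.chrom_sizes[c]):
                raise ValueError(f"{c}: CpG positions outside chromosome")
            self.cpg_pos[c] = pos

    @classmethod
    def random(cls, chrom_sizes: dict[str, int], mean_spacing: int = DEFAULT_SPACING,
               seed: int = 0) -> "GenomeSpec":
        """Geometric CpG spacing with the given mean (default 100 bp)."""
        rng = np.random.default_rng(seed)
        cpg = {}
        for c, size in chrom_sizes.items():
            n_upper = int(2.5 * size / mean_spacing) + 10
            gaps = rng.geometric(1.0 / mean_spacing, size=n_upper)
            pos = np.cumsum(gaps) - 1
            cpg[c] = pos[pos < size]
        return cls(dict(chrom_sizes), cpg)

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p in self.cpg_pos.values())

    def genome_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def sites_frame(self) -> pd.DataFrame:
        chroms, poss = [], []
        for c in sorted(self.chrom_sizes):
            chroms.extend([c] * len(self.cpg_pos[c]))
            poss.append(self.cpg_pos[c])
        return pd.DataFrame({"chrom": chroms, "pos": np.concatenate(poss) if poss else []})


@dataclass(frozen=True)
class PlantedDMR:
    """A true differential region: group 2's methylation is shifted by
    ``delta`` (hyper: delta > 0 means group 2 above group 1 is *not* the
    convention here — ``direction`` is hyper when group 1 exceeds group 2,
    i.e. delta < 0)."""

    chrom: str
    start: int
    end: int
    delta: float

    def __post_init__(self):
        if not (0 < abs(self.delta) <= 1):
            raise ValueError("delta must satisfy 0 < |delta| <= 1")
        if self.start >= self.end:
            raise ValueError("start must be < end")

    @property
    def direction(self) -> str:
        # group 1 minus group 2 difference has sign -delta
        return "hyper" if self.delta < 0 else "hypo"


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated dataset — the oracle for recovery
    tests."""

    planted: list[PlantedDMR] = field(default_factory=list)
    true_proportions: pd.DataFrame | None = None  # samples x tissues
    true_directions: pd.Series | None = None  # (chrom, pos) -> sign

    def __post_init__(self):
        if self.true_proportions is not None:
            p = self.true_proportions.to_numpy(dtype=float)
            if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1) > 1e-9):
                raise ValueError("true proportions must be on the simplex")


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters matching a mean and sd (sd capped below the
    Bernoulli bound)."""
    v = min(sd, 0.95 * np.sqrt(mean * (1 - mean))) ** 2
    k = mean * (1 - mean) / v - 1
    return mean * k, (1 - mean) * k


def simulate_methylome(
    spec: GenomeSpec,
    n_per_group: tuple[int, int] = (5, 5),
    planted: list[PlantedDMR] | None = None,
    baseline_mean: float = DEFAULT_BASELINE,
    dispersion: float = DEFAULT_PHI,
    coverage_mean: float = 30.0,
    seed: int = 0,
    group_names: tuple[str, str] = ("group1", "group2"),
) -> tuple[CpGCountMatrix, SyntheticTruth]:
    """Two-group per-CpG beta-binomial counts with planted DMRs.

    A latent mean is drawn per non-overlapping 1 kb window from a Beta
    distribution matching (baseline_mean, between-window sd 0.15), shared
    by all sites in the window and clipped to (0.01, 0.99). Inside a
    planted region, group 2's mean is shifted by that region's delta.
    Coverage is 1 + Poisson(coverage_mean - 1) per site and sample;
    methylated counts are beta-binomial with dispersion phi (phi = 0
    degenerates to binomial). Identical seeds give bit-identical output.
    """
    if not (0 < baseline_mean < 1):
        raise ValueError("baseline_mean must be in (0, 1)")
    if not (0 <= dispersion < 1):
        raise ValueError("dispersion must be in [0, 1)")
    if coverage_mean < 1:
        raise ValueError("coverage_mean must be >= 1")
    planted = list(planted or [])

    # validate planted regions: inside genome, >=1 CpG, non-overlapping
    by_chrom: dict[str, list[PlantedDMR]] = {}
    for d in planted:
        if d.chrom not in spec.chrom_sizes:
            raise ValueError(f"planted region on unknown chromosome {d.chrom}")
        pos = spec.cpg_pos[d.chrom]
        if not np.any((pos >= d.start) & (pos < d.end)):
            raise ValueError(f"planted region {d.chrom}:{d.start}-{d.end} contains no CpG")
        by_chrom.setdefault(d.chrom, []).append(d)
    for c, ds in by_chrom.items():
        ds_sorted = sorted(ds, key=lambda d: d.start)
        for a, b in zip(ds_sorted, ds_sorted[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping planted regions on {c}")

    rng = np.random.default_rng(seed)
    n1, n2 = n_per_group
    n_samples = n1 + n2
    a0, b0 = _beta_params(baseline_mean, LATENT_SD)

    chroms_all, pos_all, mu1_all, mu2_all = [], [], [], []
    for c in sorted(spec.chrom_sizes):
        pos = spec.cpg_pos[c]
        if len(pos) == 0:
            continue
        n_windows = spec.chrom_sizes[c] // LATENT_WINDOW_BP + 1
        win_mu = rng.beta(a0, b0, size=n_windows)
        mu = np.clip(win_mu[pos // LATENT_WINDOW_BP], 0.01, 0.99)
        mu1 = mu.copy()
        mu2 = mu.copy()
        for d in by_chrom.get(c, []):
            inside = (pos >= d.start) & (pos < d.end)
            mu2[inside] = np.clip(mu2[inside] + d.delta, 0.01, 0.99)
        chroms_all.extend([c] * len(pos))
        pos_all.append(pos)
        mu1_all.append(mu1)
        mu2_all.append(mu2)

    pos_arr = np.concatenate(pos_all)
    mu1 = np.concatenate(mu1_all)
    mu2 = np.concatenate(mu2_all)
    n_sites = len(pos_arr)

    total = 1 + rng.poisson(coverage_mean - 1.0, size=(n_sites, n_samples))
    mu_mat = np.column_stack([np.repeat(mu1[:, None], n1, axis=1),
                              np.repeat(mu2[:, None], n2, axis=1)])
    if dispersion > 0:
        a = mu_mat * (1 - dispersion) / dispersion
        b = (1 - mu_mat) * (1 - dispersion) / dispersion
        p = rng.beta(a, b)
    else:
        p = mu_mat
    meth = rng.binomial(total, p)

    samples = [f"{group_names[0]}_{i + 1}" for i in range(n1)] + [
        f"{group_names[1]}_{i + 1}" for i in range(n2)
    ]
    groups = {s: (group_names[0] if i < n1 else group_names[1]) for i, s in enumerate(samples)}
    counts = CpGCountMatrix(np.asarray(chroms_all, dtype=object), pos_arr, meth, total,
                            samples, groups)
    truth = SyntheticTruth(planted=planted)
    return counts, truth


def simulate_mixture(
    panel: ReferencePanel,
    proportions,
    coverage: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Observed marker methylation of a convex tissue mixture.

    With ``noise_sd = 0`` and ``coverage = None`` (infinite reads) the
    result is exactly ``R @ p``. Otherwise Gaussian noise (sd
    ``noise_sd``) is added and/or counts are binomially resampled at the
    stated coverage; values are clipped to [0, 1].
    """
    p = np.asarray(proportions, dtype=float)
    R = panel.fractions.to_numpy(dtype=float)
    if p.shape != (R.shape[1],):
        raise ValueError(f"proportion vector length {p.shape} != {R.shape[1]} tissues")
    if np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
        raise ValueError("proportions must be on the simplex")
    m = R @ p
    rng = np.random.default_rng(seed)
    if coverage is not None:
        if coverage < 1:
            raise ValueError("coverage must be >= 1")
        n = int(round(coverage))
        m = rng.binomial(n, np.clip(m, 0, 1)) / n
    if noise_sd > 0:
        m = m + rng.normal(0.0, noise_sd, size=m.shape)
    return np.clip(m, 0.0, 1.0)


def simulate_external_summary(
    dml: pd.DataFrame,
    concordant_fraction: float = 0.8,
    significant_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """EWAS-like external per-site summary for concordance testing.

    Each site shared with the internal result receives a direction equal
    to the internal sign with probability ``concordant_fraction``
    (flipped otherwise) and an independent significance flag.
    """
    if not (0 <= concordant_fraction <= 1 and 0 <= significant_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    if len(dml) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "direction", "significant"])
    rng = np.random.default_rng(seed)
    sign = np.where(dml["diff"].to_numpy() >= 0, 1, -1)
    keep = rng.random(len(dml)) < concordant_fraction
    out_sign = np.where(keep, sign, -sign)
    sig = rng.random(len(dml)) < significant_fraction
    return pd.DataFrame(
        {"chrom": dml["chrom"].to_numpy(), "pos": dml["pos"].to_numpy(),
         "direction": out_sign, "significant": sig}
    )


# ---------------------------------------------------------------------------
# annotation fixture


def make_annotation_fixture(
    spec: GenomeSpec, n_genes: int, seed: int = 0,
    gene_len_range: tuple[int, int] = (2000, 8000),
    cgi_prob_tss: float = 0.5,
) -> tuple[AnnotationSet, pd.DataFrame]:
    """Non-overlapping gene models plus CpG-island context.

    Returns an :class:`AnnotationSet` holding two independent layers —
    the gene layer (promoter / 1to5kb / 5UTR / exon / intron / 3UTR /
    intergenic) and the CGI layer (CGI / shore / shelf / open_sea) — each
    of which partitions the genome exactly once under the construction
    precedence (gene-body parts over promoter over 1to5kb over
    intergenic), and the gene model table (chrom, start, end, strand,
    gene_id).
    """
    rng = np.random.default_rng(seed)
    margin = 5500  # room for 1-5 kb upstream regions between genes
    genes = []
    chroms = sorted(spec.chrom_sizes)
    weights = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    per_chrom = {c: [] for c in chroms}
    n_assigned = rng.multinomial(n_genes, weights / weights.sum())
    gid = 0
    for c, k in zip(chroms, n_assigned):
        size = spec.chrom_sizes[c]
        cursor = margin
        lens = rng.integers(gene_len_range[0], gene_len_range[1] + 1, size=k)
        # random non-overlapping placement: distribute leftover space as gaps
        need = int(lens.sum()) + (k + 1) * margin
        if need > size:
            raise ValueError(f"{c}: cannot place {k} genes without overlap")
        slack = size - need
        gaps = rng.multinomial(slack, np.ones(k + 1) / (k + 1)) if k else []
        for i in range(k):
            cursor += int(gaps[i])
            start = cursor
            end = start + int(lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append((c, start, end, strand, f"gene{gid}"))
            per_chrom[c].append((start, end, strand))
            cursor = end + margin
            gid += 1
    gene_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "strand", "gene_id"])

    rows = []

    def add(chrom, ivs, feature, strand="."):
        for s, e in ivs:
            if s < e:
                rows.append((chrom, int(s), int(e), feature, ".", strand))

    for c in chroms:
        size = spec.chrom_sizes[c]
        covered = []  # gene-layer precedence accumulator
        sub = gene_df[gene_df["chrom"] == c]
        # gene-body partition: 5'UTR (200 bp), exons/introns, 3'UTR (300 bp)
        for r in sub.itertuples(index=False):
            L = r.end - r.start
            u5, u3 = 200, 300
            body_s, body_e = r.start + u5, r.end - u3
            if r.strand == "-":
                body_s, body_e = r.start + u3, r.end - u5
                add(c, [(r.start, r.start + u3)], "3UTR", r.strand)
                add(c, [(r.end - u5, r.end)], "5UTR", r.strand)
            else:
                add(c, [(r.start, r.start + u5)], "5UTR", r.strand)
                add(c, [(r.end - u3, r.end)], "3UTR", r.strand)
            # three exons separated by two introns inside the remaining body
            inner = body_e - body_s
            bounds = np.sort(rng.choice(np.arange(1, inner), size=4, replace=False)) + body_s
            pieces = [(body_s, bounds[0]), (bounds[0], bounds[1]), (bounds[1], bounds[2]),
                      (bounds[2], bounds[3]), (bounds[3], body_e)]
            for i, (s, e) in enumerate(pieces):
                add(c, [(s, e)], "exon" if i % 2 == 0 else "intron", r.strand)
            covered.append((r.start, r.end))
            # promoter and 1-5 kb upstream, strand aware
            if r.strand == "+":
                prom = (max(0, r.start - 1000), r.start)
                up = (max(0, r.start - 5000), max(0, r.start - 1000))
            else:
                prom = (r.end, min(size, r.end + 1000))
                up = (min(size, r.end + 1000), min(size, r.end + 5000))
            body = merge_intervals(covered)
            for iv, feat in ((prom, "promoter"), (up, "1to5kb")):
                if iv[0] < iv[1]:
                    clipped = subtract_intervals([iv], body)
                    add(c, clipped, feat, r.strand)
                    covered.extend(map(tuple, clipped))
        inter = complement_intervals(covered, size) if covered else complement_intervals([], size)
        add(c, inter, "intergenic")

        # CGI layer: islands near a subset of TSSs plus a few random ones
        islands = []
        for r in sub.itertuples(index=False):
            if rng.random() < cgi_prob_tss:
                tss = r.start if r.strand == "+" else r.end
                islands.append((max(0, tss - 400), min(size, tss + 400)))
        for _ in range(max(1, len(sub) // 3)):
            s = int(rng.integers(0, max(1, size - 800)))
            islands.append((s, s + 800))
        islands = merge_intervals(islands) if islands else np.empty((0, 2), dtype=np.int64)
        add(c, islands, "CGI")
        shores_raw = [(max(0, s - 2000), min(size, e + 2000)) for s, e in islands]
        shores = subtract_intervals(shores_raw, islands) if len(islands) else []
        add(c, shores, "shore")
        shelves_raw = [(max(0, s - 4000), min(size, e + 4000)) for s, e in islands]
        taken = merge_intervals(list(islands) + list(map(tuple, shores))) if len(islands) else []
        shelves = subtract_intervals(shelves_raw, taken) if len(islands) else []
        add(c, shelves, "shelf")
        cgi_all = merge_intervals(list(islands) + list(map(tuple, shores)) + list(map(tuple, shelves))) if len(islands) else []
        add(c, complement_intervals(cgi_all, size), "open_sea")

    ann = AnnotationSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "feature", "name", "strand"]))
    return ann, gene_df


# ---------------------------------------------------------------------------
# reference panel


def synthetic_reference_panel(
    n_type1: int = 140,
    n_type2: int = 360,
    tissues: list[str] | None = None,
    seed: int = 0,
    marker_len: int = 500,
) -> ReferencePanel:
    """Marker x tissue methylation fractions with the two marker flavours
    used for cfDNA deconvolution: Type I loci stand out in exactly one
    tissue against a homogeneous background; Type II loci vary across all
    tissues."""
    if tissues is None:
        tissues = [
            "liver", "lung", "esophagus", "heart", "pancreas", "colon",
            "small_intestine", "adipose", "adrenal", "brain",
            "t_cells", "b_cells", "neutrophils", "placenta",
        ]
    T = len(tissues)
    if T < 2:
        raise ValueError("panel needs at least two tissues")
    rng = np.random.default_rng(seed)
    rows = []
    classes = []
    for i in range(n_type1):
        base = rng.uniform(0.05, 0.25) if rng.random() < 0.5 else rng.uniform(0.75, 0.95)
        target = 1 - base + rng.normal(0, 0.03)
        beta = np.clip(base + rng.normal(0, 0.02, size=T), 0, 1)
        beta[i % T] = np.clip(target, 0, 1)
        rows.append(beta)
        classes.append("TypeI")
    for _ in range(n_type2):
        rows.append(rng.uniform(0.05, 0.95, size=T))
        classes.append("TypeII")
    frac = pd.DataFrame(np.asarray(rows), columns=tissues)
    n = len(frac)
    markers = pd.DataFrame(
        {"chrom": ["chrM"] * n,
         "start": np.arange(n, dtype=np.int64) * (marker_len * 2),
         "end": np.arange(n, dtype=np.int64) * (marker_len * 2) + marker_len}
    )
    return ReferencePanel(markers, frac, pd.Series(classes))
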