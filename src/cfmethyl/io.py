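"""Readers, writers, and core containers for methylome data.

Internal coordinates are uniformly 0-based half-open; only the Bismark
coverage dialect is 1-based at the file boundary. Gzip is handled
transparently for every format (by file suffix).

Containers
----------
CpGCountMatrix
    Per-site, per-sample methylated / total read counts — the universal
    input to testing, region summaries, and deconvolution.
AnnotationSet
    BED-style feature intervals with a closed feature vocabulary.
ReferencePanel
    Marker x tissue methylation-fraction matrix used for
    tissue-of-origin deconvolution.
"""

from __future__ import annotations

import gzip
import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEATURE_CLASSES = (
    "promoter",
    "1to5kb",
    "5UTR",
    "exon",
    "intron",
    "3UTR",
    "intergenic",
    "CGI",
    "shore",
    "shelf",
    "open_sea",
)

GENE_LAYER = ("promoter", "1to5kb", "5UTR", "exon", "intron", "3UTR", "intergenic")
CGI_LAYER = ("CGI", "shore", "shelf", "open_sea")


class FormatError(ValueError):
    """Malformed input; the message carries file/line context."""


def _open_text(src, mode: str = "rt"):
    """Open a path (gzip by suffix) or pass a file object through."""
    if isinstance(src, (str, Path)):
        p = Path(src)
        if p.suffix == ".gz":
            return gzip.open(p, mode)
        return open(p, mode)
    return _io.TextIOWrapper(src) if isinstance(src, (_io.RawIOBase, _io.BufferedIOBase)) else src


# ---------------------------------------------------------------------------
# containers


@dataclass
class CpGCountMatrix:
    """Sorted per-CpG methylated/total counts across samples.

    Parameters
    ----------
    chrom, pos
        Site coordinates, 0-based; (chrom, pos) must be unique and sorted.
    meth, total
        ``(n_sites, n_samples)`` integer count arrays with
        ``0 <= meth <= total`` everywhere; ``total == 0`` marks a site
        unobserved in that sample.
    samples
        Sample identifiers, one per column.
    groups
        Optional mapping sample -> group label; required for two-group
        testing.
    """

    chrom: np.ndarray
    pos: np.ndarray
    meth: np.ndarray
    total: np.ndarray
    samples: list[str]
    groups: dict[str, str] | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.meth.ndim == 1:
            self.meth = self.meth[:, None]
            self.total = self.total[:, None]
        n, s = self.meth.shape
        if self.total.shape != (n, s) or len(self.chrom) != n or len(self.pos) != n:
            raise ValueError("inconsistent CpGCountMatrix dimensions")
        if len(self.samples) != s:
            raise ValueError("sample names do not match count columns")
        if np.any(self.meth < 0) or np.any(self.meth > self.total):
            raise ValueError("counts must satisfy 0 <= meth <= total")
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("sites must be sorted by (chrom, pos)")
        key = pd.MultiIndex.from_arrays([self.chrom.astype(str), self.pos])
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos) sites; strand-merge upstream")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_columns(self, label: str) -> np.ndarray:
        if self.groups is None:
            raise ValueError("no group labels attached")
        cols = [i for i, s in enumerate(self.samples) if self.groups.get(s) == label]
        if not cols:
            raise ValueError(f"no samples in group {label!r}")
        return np.asarray(cols)

    def group_labels(self) -> list[str]:
        if self.groups is None:
            raise ValueError("no group labels attached")
        seen: list[str] = []
        for s in self.samples:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom.astype(str), "pos": self.pos})


@dataclass
class AnnotationSet:
    """Feature intervals with classes from the closed vocabulary."""

    df: pd.DataFrame  # chrom, start, end, feature, name, strand

    def __post_init__(self):
        req = {"chrom", "start", "end", "feature"}
        if not req.issubset(self.df.columns):
            raise ValueError(f"annotation frame needs columns {sorted(req)}")
        df = self.df.copy()
        for col, default in (("name", "."), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        if (df["start"] >= df["end"]).any():
            bad = df.index[(df["start"] >= df["end"])][0]
            raise FormatError(f"interval start >= end at row {bad}")
        unknown = set(df["feature"]) - set(FEATURE_CLASSES)
        if unknown:
            raise FormatError(f"unknown feature classes: {sorted(unknown)}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    def subset(self, features: Iterable[str]) -> "AnnotationSet":
        feats = set(features)
        return AnnotationSet(self.df[self.df["feature"].isin(feats)].reset_index(drop=True))

    def feature_intervals(self, feature: str) -> dict[str, np.ndarray]:
        sub = self.df[self.df["feature"] == feature]
        return {
            c: g[["start", "end"]].to_numpy(dtype=np.int64)
            for c, g in sub.groupby("chrom", sort=True)
        }


@dataclass
class ReferencePanel:
    """Tissue-specific methylation markers.

    ``fractions`` is a markers x tissues DataFrame of methylation
    fractions in [0, 1]; ``markers`` carries coordinates; ``marker_class``
    (TypeI / TypeII / unclassified) may be assigned by
    :func:`cfmethyl.deconvolve.select_markers`.
    """

    markers: pd.DataFrame  # chrom, start, end
    fractions: pd.DataFrame  # index aligned with markers, columns = tissues
    marker_class: pd.Series | None = None

    def __post_init__(self):
        if len(self.markers) != len(self.fractions):
            raise ValueError("marker table and fraction matrix differ in length")
        if self.fractions.isna().any().any():
            raise ValueError("reference panel has missing fractions")
        vals = self.fractions.to_numpy(dtype=float)
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("panel fractions must lie in [0, 1]")
        if self.fractions.columns.duplicated().any():
            raise ValueError("tissue names must be unique")
        if self.marker_class is None:
            self.marker_class = pd.Series("unclassified", index=self.fractions.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.fractions.columns)

    @property
    def n_markers(self) -> int:
        return len(self.fractions)


# ---------------------------------------------------------------------------
# Bismark coverage


def parse_bismark_cov(src) -> pd.DataFrame:
    """Parse one Bismark ``.cov`` file into a per-site count frame.

    Input columns are chrom, start (1-based), end, methylation %, count
    methylated, count unmethylated. Output columns are ``chrom``, ``pos``
    (0-based), ``meth``, ``total``. Rows with zero coverage are dropped
    (count reported in ``df.attrs['n_dropped']`` and the log); a reported
    percentage off by more than 0.5 from ``100*M/N`` triggers a warning
    and the value recomputed from counts is kept.
    """
    fh = _open_text(src)
    rows = []
    n_dropped = 0
    for lineno, line in enumerate(fh, start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 6:
            raise FormatError(f"line {lineno}: expected 6 columns, got {len(parts)}")
        chrom, start, _end, pct, m, u = parts[:6]
        try:
            start_i, m_i, u_i = int(start), int(m), int(u)
            pct_f = float(pct)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        if m_i < 0 or u_i < 0:
            raise FormatError(f"line {lineno}: negative count")
        n = m_i + u_i
        if n == 0:
            n_dropped += 1
            continue
        if abs(pct_f - 100.0 * m_i / n) > 0.5:
            logger.warning(
                "line %d: reported %%=%.3f disagrees with counts (%.3f); using counts",
                lineno, pct_f, 100.0 * m_i / n,
            )
        rows.append((chrom, start_i - 1, m_i, n))
    if n_dropped:
        logger.info("dropped %d zero-coverage rows", n_dropped)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    df.attrs["n_dropped"] = n_dropped
    return df


def write_bismark_cov(counts: pd.DataFrame | CpGCountMatrix, dest, sample: str | None = None) -> None:
    """Write a Bismark coverage file (1-based, both coordinates = site)."""
    if isinstance(counts, CpGCountMatrix):
        if sample is None:
            raise ValueError("sample name required when writing from a matrix")
        j = counts.samples.index(sample)
        df = pd.DataFrame(
            {"chrom": counts.chrom.astype(str), "pos": counts.pos,
             "meth": counts.meth[:, j], "total": counts.total[:, j]}
        )
        df = df[df["total"] > 0]
    else:
        df = counts
    own = isinstance(dest, (str, Path))
    fh = _open_text(dest, "wt")
    try:
        for chrom, pos, m, n in df[["chrom", "pos", "meth", "total"]].itertuples(index=False):
            pct = 100.0 * m / n
            fh.write(f"{chrom}\t{pos + 1}\t{pos + 1}\t{pct:g}\t{m}\t{n - m}\n")
    finally:
        if own:
            fh.close()


def combine_coverage(
    per_sample: Mapping[str, pd.DataFrame], groups: Mapping[str, str] | None = None
) -> CpGCountMatrix:
    """Merge per-sample coverage frames on the union of sites.

    Sites missing from a sample get total = 0 and contribute nothing to
    that sample's likelihood downstream.
    """
    samples = list(per_sample)
    frames = []
    for s in samples:
        df = per_sample[s]
        key = pd.MultiIndex.from_arrays([df["chrom"].astype(str), df["pos"]])
        if key.duplicated().any():
            raise ValueError(f"sample {s!r}: duplicate (chrom, pos); strand-merge upstream")
        frames.append(df.set_index(["chrom", "pos"])[["meth", "total"]])
    merged = pd.concat(frames, axis=1, keys=samples).fillna(0).astype(np.int64)
    merged = merged.sort_index()
    chrom = merged.index.get_level_values(0).to_numpy(dtype=object)
    pos = merged.index.get_level_values(1).to_numpy(dtype=np.int64)
    meth = np.column_stack([merged[(s, "meth")].to_numpy() for s in samples])
    total = np.column_stack([merged[(s, "total")].to_numpy() for s in samples])
    return CpGCountMatrix(chrom, pos, meth, total, samples, dict(groups) if groups else None)


# ---------------------------------------------------------------------------
# BED / bedGraph / panel TSV


def parse_bed_annotation(src) -> AnnotationSet:
    """Parse BED6 (name column = feature class) into an AnnotationSet."""
    fh = _open_text(src)
    rows = []
    for lineno, line in enumerate(fh, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 4:
            raise FormatError(f"line {lineno}: BED needs >=4 columns")
        chrom, start, end, feature = parts[:4]
        strand = parts[5] if len(parts) > 5 else "."
        try:
            s, e = int(start), int(end)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        if s >= e:
            raise FormatError(f"line {lineno}: start >= end")
        if feature not in FEATURE_CLASSES:
            raise FormatError(f"line {lineno}: unknown feature class {feature!r}")
        rows.append((chrom, s, e, feature, ".", strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "feature", "name", "strand"])
    return AnnotationSet(df)


def write_bed_annotation(ann: AnnotationSet, dest) -> None:
    own = isinstance(dest, (str, Path))
    fh = _open_text(dest, "wt")
    try:
        for r in ann.df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.feature}\t.\t{r.strand}\n")
    finally:
        if own:
            fh.close()


def parse_bedgraph(src) -> pd.Series:
    """Read a methylation track: chrom, start, end, fraction -> Series
    indexed by (chrom, pos) with one entry per covered position start."""
    fh = _open_text(src)
    chroms, poss, vals = [], [], []
    for lineno, line in enumerate(fh, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"line {lineno}: bedGraph needs 4 columns")
        try:
            s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        if s >= e:
            raise FormatError(f"line {lineno}: start >= end")
        chroms.append(parts[0])
        poss.append(s)
        vals.append(v)
    idx = pd.MultiIndex.from_arrays([chroms, poss], names=["chrom", "pos"])
    return pd.Series(vals, index=idx, name="fraction").sort_index()


def write_bedgraph(track: pd.Series, dest) -> None:
    own = isinstance(dest, (str, Path))
    fh = _open_text(dest, "wt")
    try:
        for (chrom, pos), v in track.items():
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{v:g}\n")
    finally:
        if own:
            fh.close()


def parse_marker_panel(src) -> ReferencePanel:
    """Parse the marker-panel TSV: chrom, start, end, [class,] tissue columns."""
    fh = _open_text(src)
    df = pd.read_csv(fh, sep="\t")
    if df.empty and len(df.columns) < 4:
        raise FormatError("panel file has no tissue columns")
    meta_cols = ["chrom", "start", "end"]
    for c in meta_cols:
        if c not in df.columns:
            raise FormatError(f"panel missing column {c!r}")
    has_class = "marker_class" in df.columns
    tissue_cols = [c for c in df.columns if c not in meta_cols + ["marker_class"]]
    frac = df[tissue_cols].astype(float)
    bad = ~((frac >= 0) & (frac <= 1))
    if bad.any().any():
        row = int(np.argwhere(bad.to_numpy())[0][0])
        raise FormatError(f"line {row + 2}: fraction outside [0, 1]")
    if (df["start"] >= df["end"]).any():
        row = int(df.index[(df["start"] >= df["end"])][0])
        raise FormatError(f"line {row + 2}: start >= end")
    return ReferencePanel(
        markers=df[meta_cols].reset_index(drop=True),
        fractions=frac.reset_index(drop=True),
        marker_class=df["marker_class"].reset_index(drop=True) if has_class else None,
    )


def write_marker_panel(panel: ReferencePanel, dest) -> None:
    df = pd.concat(
        [panel.markers.reset_index(drop=True),
         pd.Series(panel.marker_class.to_numpy(), name="marker_class"),
         panel.fractions.reset_index(drop=True)],
        axis=1,
    )
    own = isinstance(dest, (str, Path))
    fh = _open_text(dest, "wt")
    try:
        df.to_csv(fh, sep="\t", index=False)
    finally:
        if own:
            fh.close()
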