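"""Genomic-feature assignment and fold enrichment for regions.

A region is assigned every feature class it overlaps by at least 1 bp
(multi-assignment, as genome annotation tools conventionally report);
regions overlapping nothing are intergenic. Fold enrichment compares the
share of assignments landing in a feature with the share of genome
length the feature occupies (merged, so overlapping intervals are not
double-counted).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AnnotationSet, GENE_LAYER
from .intervals import distance_to_intervals, intervals_overlapping, merge_intervals, total_length
from .simulate import GenomeSpec

__all__ = ["annotate_regions", "fold_enrichment", "classify_cgi_context"]


def annotate_regions(regions: pd.DataFrame, annotation: AnnotationSet,
                     features: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Assign each region every overlapped feature class.

    Parameters
    ----------
    regions
        Frame with chrom, start, end (0-based half-open).
    features
        Feature classes to consider (default: the gene layer).

    Returns a long frame (region_index, chrom, start, end, feature) with
    one row per assignment; regions hitting no considered feature are
    assigned ``intergenic``.
    """
    feats = tuple(features) if features is not None else GENE_LAYER
    n = len(regions)
    assigned = [[] for _ in range(n)]
    chrom_arr = regions["chrom"].to_numpy(dtype=object)
    q = regions[["start", "end"]].to_numpy(dtype=np.int64)
    for feature in feats:
        per_chrom = annotation.feature_intervals(feature)
        for c, iv in per_chrom.items():
            mask = chrom_arr.astype(str) == c
            if not mask.any():
                continue
            rows = np.flatnonzero(mask)
            hit = intervals_overlapping(q[rows], iv)
            for r in rows[hit]:
                assigned[r].append(feature)
    rows_out = []
    for i in range(n):
        hits = assigned[i] or ["intergenic"]
        for f in hits:
            rows_out.append((i, chrom_arr[i], int(q[i, 0]), int(q[i, 1]), f))
    return pd.DataFrame(rows_out, columns=["region_index", "chrom", "start", "end", "feature"])


def fold_enrichment(
    regions: pd.DataFrame,
    annotation: AnnotationSet,
    genome: GenomeSpec,
    features: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Observed versus genomic-background feature occupancy.

    expected fraction = merged bp of the feature / genome length;
    observed fraction = share of region-feature assignments;
    fold = observed / expected.
    """
    feats = tuple(features) if features is not None else GENE_LAYER
    genome_len = genome.genome_length()
    if genome_len <= 0:
        raise ValueError("genome length must be positive")
    assignments = annotate_regions(regions, annotation, feats)
    n_total = len(assignments)
    rows = []
    for feature in feats:
        per_chrom = annotation.feature_intervals(feature)
        bp = sum(total_length(iv) for iv in per_chrom.values())
        n_assigned = int((assignments["feature"] == feature).sum())
        if bp == 0:
            if n_assigned > 0:
                raise ValueError(
                    f"feature {feature!r} has zero genomic span but {n_assigned} assignments"
                )
            continue
        expected = bp / genome_len
        observed = n_assigned / n_total if n_total else 0.0
        rows.append((feature, n_assigned, observed, expected, observed / expected))
    return pd.DataFrame(
        rows, columns=["feature", "n_assigned", "observed_frac", "expected_frac", "fold"]
    )


def classify_cgi_context(loci: pd.DataFrame, cgi: pd.DataFrame | AnnotationSet) -> pd.Series:
    """CpG-island context of point loci.

    island: inside a (merged) CGI; shore: within 2 kb of an island edge;
    shelf: within (2, 4] kb; open_sea otherwise. The nearest island wins
    ties between two islands automatically (minimum distance).

    ``loci`` needs chrom and pos columns; ``cgi`` is a frame of CGI
    intervals (chrom, start, end) or an AnnotationSet containing CGI
    features.
    """
    if isinstance(cgi, AnnotationSet):
        cgi = cgi.df[cgi.df["feature"] == "CGI"][["chrom", "start", "end"]]
    out = np.full(len(loci), "open_sea", dtype=object)
    chrom_arr = loci["chrom"].to_numpy(dtype=object)
    pos = loci["pos"].to_numpy(dtype=np.int64)
    for c, sub in cgi.groupby("chrom"):
        mask = chrom_arr.astype(str) == str(c)
        if not mask.any():
            continue
        iv = merge_intervals(sub[["start", "end"]].to_numpy(dtype=np.int64))
        d = distance_to_intervals(pos[mask], iv)
        cls = np.where(d == 0, "island",
                       np.where(d <= 2000, "shore",
                                np.where(d <= 4000, "shelf", "open_sea")))
        out[np.flatnonzero(mask)] = cls
    return pd.Series(out, index=loci.index, name="cgi_context")
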