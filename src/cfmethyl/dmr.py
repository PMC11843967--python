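"""Segment per-site test results into differentially methylated regions.

A DMR is a run of CpGs with sub-threshold p-values: consecutive
significant sites are chained while the bp gap between them stays within
``merge_dist``, the run is extended to [first site, last site + 1), and
candidates are kept only if they pass all of — minimum bp length,
minimum CpG count (all tested CpGs inside the bounds), minimum fraction
of significant CpGs, and a coverage-weighted group difference exceeding
``delta``. Defaults mirror the published calling rules (p < 0.05,
difference > 0.1, >= 50 bp, >= 4 CpGs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CpGCountMatrix
from .intervals import points_in_intervals

__all__ = ["call_dmr", "region_methylation_matrix"]


def call_dmr(
    records: pd.DataFrame,
    p_threshold: float = 0.05,
    delta: float = 0.1,
    min_len: int = 50,
    min_cg: int = 4,
    merge_dist: int = 100,
    pct_sig: float = 0.5,
) -> pd.DataFrame:
    """Call DMRs from sorted per-site test records.

    Returns a frame with columns chrom, start, end, length, nCG,
    meanMethy1, meanMethy2, diff_methy, areaStat, direction; the region
    end is exclusive (last member CpG + 1). Weighted means use the
    ``n_total`` coverage column when present, equal weights otherwise.
    """
    if len(records) == 0:
        return _empty_dmr_frame()
    chrom = records["chrom"].to_numpy(dtype=object)
    pos = records["pos"].to_numpy(dtype=np.int64)
    order = np.lexsort((pos, chrom.astype(str)))
    if not np.array_equal(order, np.arange(len(pos))):
        raise ValueError("records must be sorted by (chrom, pos)")

    weights = (
        records["n_total"].to_numpy(dtype=float)
        if "n_total" in records.columns
        else np.ones(len(records))
    )
    pvals = records["pval"].to_numpy(dtype=float)
    mu1 = records["mu1"].to_numpy(dtype=float)
    mu2 = records["mu2"].to_numpy(dtype=float)
    stat = records["stat"].to_numpy(dtype=float)

    out = []
    for c in pd.unique(chrom.astype(str)):
        idx = np.flatnonzero(chrom.astype(str) == c)
        p_c = pos[idx]
        marked = np.flatnonzero(pvals[idx] < p_threshold)
        if len(marked) == 0:
            continue
        # chain marked sites while the gap to the next stays <= merge_dist
        gaps = np.diff(p_c[marked])
        breaks = np.flatnonzero(gaps > merge_dist)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(marked) - 1]])
        for s_i, e_i in zip(starts, ends):
            first, last = marked[s_i], marked[e_i]
            start_bp = int(p_c[first])
            end_bp = int(p_c[last]) + 1
            members = idx[first : last + 1]  # all tested CpGs in bounds
            n_cg = len(members)
            n_sig = int((pvals[members] < p_threshold).sum())
            length = end_bp - start_bp
            w = weights[members]
            m1 = float(np.average(mu1[members], weights=w))
            m2 = float(np.average(mu2[members], weights=w))
            d = m1 - m2
            if (
                length >= min_len
                and n_cg >= min_cg
                and n_sig / n_cg >= pct_sig
                and abs(d) > delta
            ):
                out.append(
                    (c, start_bp, end_bp, length, n_cg, m1, m2, d,
                     float(stat[members].sum()),
                     "hyper" if d > 0 else "hypo")
                )
    if not out:
        return _empty_dmr_frame()
    return pd.DataFrame(
        out,
        columns=["chrom", "start", "end", "length", "nCG", "meanMethy1",
                 "meanMethy2", "diff_methy", "areaStat", "direction"],
    )


def _empty_dmr_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "length", "nCG", "meanMethy1",
                 "meanMethy2", "diff_methy", "areaStat", "direction"]
    )


def region_methylation_matrix(counts: CpGCountMatrix, regions: pd.DataFrame) -> pd.DataFrame:
    """Region x sample matrix of weighted methylation.

    Entry (r, s) is sum(M)/sum(N) over the CpGs of region r in sample s;
    NaN where the sample has no coverage in the region.
    """
    chrom_str = counts.chrom.astype(str)
    mat = np.full((len(regions), counts.n_samples), np.nan)
    names = []
    for i, r in enumerate(regions.itertuples(index=False)):
        inside = (chrom_str == r.chrom) & points_in_intervals(
            counts.pos, [(r.start, r.end)]
        )
        names.append(f"{r.chrom}:{r.start}-{r.end}")
        if not inside.any():
            continue
        m = counts.meth[inside].sum(axis=0).astype(float)
        n = counts.total[inside].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mat[i] = np.where(n > 0, m / np.maximum(n, 1e-300), np.nan)
    return pd.DataFrame(mat, index=names, columns=counts.samples)
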