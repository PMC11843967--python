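"""Scale-regions metagene methylation profiles.

Each gene contributes a fixed-width upstream flank, a body linearly
rescaled to a common number of bins, and a downstream flank (the
scale-regions convention of genome-browser matrix tools); minus-strand
genes are reversed so bin 0 is always 5'-most. Bin values are unweighted
means of the site fractions falling in the bin (a coverage-weighted mode
is available), empty bins stay missing, and the profile is the
unweighted mean over genes at each bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MetageneProfile", "average_tracks", "metagene_profile"]


@dataclass
class MetageneProfile:
    """Per-bin mean methylation over genes.

    ``values`` has length n_flank + n_body + n_flank (NaN where no gene
    contributed); ``n_genes`` counts contributing genes per bin;
    ``segments`` labels each bin upstream / body / downstream.
    """

    values: np.ndarray
    n_genes: np.ndarray
    n_flank: int
    n_body: int
    flank_bp: float

    @property
    def segments(self) -> np.ndarray:
        return np.array(
            ["upstream"] * self.n_flank + ["body"] * self.n_body + ["downstream"] * self.n_flank
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": np.arange(len(self.values)), "segment": self.segments,
             "mean_methylation": self.values, "n_genes": self.n_genes}
        )


def average_tracks(tracks: list[pd.Series]) -> pd.Series:
    """Per-site unweighted mean over the tracks that define the site."""
    if not tracks:
        raise ValueError("need at least one track")
    cat = pd.concat(tracks)
    return cat.groupby(level=[0, 1]).mean().sort_index()


def metagene_profile(
    track: pd.Series,
    genes: pd.DataFrame,
    flank: int = 10_000,
    n_body: int = 100,
    n_flank: int = 100,
    weights: pd.Series | None = None,
) -> MetageneProfile:
    """Scale-regions profile of a site->fraction track over gene models.

    Parameters
    ----------
    track
        Series indexed by (chrom, pos) with methylation fractions.
    genes
        Frame with chrom, start, end, strand.
    flank
        Flank width in bp on each side (upstream of the TSS and
        downstream of the TES, default 10 kb).
    weights
        Optional per-site weights (e.g. coverage) aligned with the
        track index; default equal weights within bins.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if len(genes) == 0:
        raise ValueError("no genes given")
    n_bins = 2 * n_flank + n_body
    acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins, dtype=np.int64)
    flank_w = flank / n_flank if n_flank else 0.0
    if weights is None:
        weights = pd.Series(1.0, index=track.index)

    by_chrom = {c: g.sort_index() for c, g in track.groupby(level=0)}
    w_by_chrom = {c: weights.loc[g.index] for c, g in by_chrom.items()}

    for r in genes.itertuples(index=False):
        if r.chrom not in by_chrom:
            continue
        sub = by_chrom[r.chrom]
        pos = sub.index.get_level_values(1).to_numpy(dtype=np.int64)
        vals = sub.to_numpy(dtype=float)
        w = w_by_chrom[r.chrom].to_numpy(dtype=float)
        lo, hi = r.start - flank, r.end + flank
        sel = (pos >= lo) & (pos < hi)
        if not sel.any():
            continue
        p, v, wv = pos[sel], vals[sel], w[sel]
        L = r.end - r.start
        bins = np.empty(len(p), dtype=np.int64)
        up = p < r.start
        down = p >= r.end
        body = ~up & ~down
        if n_flank:
            bins[up] = np.minimum(((p[up] - lo) / flank_w).astype(np.int64), n_flank - 1)
            bins[down] = n_flank + n_body + np.minimum(
                ((p[down] - r.end) / flank_w).astype(np.int64), n_flank - 1
            )
        bins[body] = n_flank + np.minimum(
            ((p[body] - r.start) * n_body // L).astype(np.int64), n_body - 1
        )
        if getattr(r, "strand", "+") == "-":
            bins = n_bins - 1 - bins
        gene_sum = np.bincount(bins, weights=v * wv, minlength=n_bins)
        gene_w = np.bincount(bins, weights=wv, minlength=n_bins)
        has = gene_w > 0
        acc[has] += gene_sum[has] / gene_w[has]
        cnt[has] += 1

    if cnt.sum() == 0:
        raise ValueError("no gene overlapped the track")
    values = np.full(n_bins, np.nan)
    values[cnt > 0] = acc[cnt > 0] / cnt[cnt > 0]
    return MetageneProfile(values, cnt, n_flank, n_body, float(flank))
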