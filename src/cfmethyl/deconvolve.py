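"""Tissue-of-origin deconvolution of cfDNA methylation.

The observed methylation of a plasma sample at tissue-discriminating
markers is modelled as a convex combination of the reference tissues'
methylation profiles. Proportions are the constrained least-squares
solution

    min_p || R p - m ||^2   s.t.  p >= 0,  sum(p) = 1,

solved by a deterministic active-set method: the passive subproblem with
the equality constraint is solved through its KKT system, negative
coordinates are driven to zero along the feasible segment
(Lawson-Hanson style), and zero coordinates re-enter when their KKT
multiplier indicates descent. There is no randomness anywhere in this
module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CpGCountMatrix, ReferencePanel
from .intervals import points_in_intervals

__all__ = [
    "TissueProportionEstimate",
    "select_markers",
    "deconvolve_qp",
    "marker_methylation",
    "compare_proportions",
]

KKT_TOL = 1e-8


@dataclass
class TissueProportionEstimate:
    """Deconvolved simplex vector for one sample."""

    proportions: pd.Series  # index = tissues
    rss: float
    n_iter: int
    active_set: tuple[str, ...]  # tissues pinned at zero

    def __post_init__(self):
        p = self.proportions.to_numpy(dtype=float)
        if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("estimate must lie on the simplex")


def select_markers(panel: ReferencePanel, tau1: float = 0.2, tau2: float = 0.1) -> pd.Series:
    """Classify panel markers as TypeI / TypeII / unclassified.

    Type I: exactly one tissue's methylation departs from the mean of
    the remaining tissues by at least ``tau1`` (a single-tissue
    signature). Type II: not Type I, but the across-tissue sd is at
    least ``tau2`` (informative through joint variability). Everything
    else is unclassified.
    """
    R = panel.fractions.to_numpy(dtype=float)
    K, T = R.shape
    if T < 2:
        raise ValueError("marker classification needs at least two tissues")
    tot = R.sum(axis=1, keepdims=True)
    mean_rest = (tot - R) / (T - 1)
    gaps = np.abs(R - mean_rest)
    n_extreme = (gaps >= tau1).sum(axis=1)
    sd = R.std(axis=1, ddof=0)
    cls = np.where(n_extreme == 1, "TypeI",
                   np.where(sd >= tau2, "TypeII", "unclassified"))
    return pd.Series(cls, index=panel.fractions.index, name="marker_class")


def _solve_kkt(RtR: np.ndarray, Rtm: np.ndarray, free: np.ndarray) -> np.ndarray:
    """Equality-constrained least squares on the free coordinates via the
    KKT system [2 R'R  1; 1' 0]."""
    k = int(free.sum())
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = 2.0 * RtR[np.ix_(free, free)]
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    rhs = np.concatenate([2.0 * Rtm[free], [1.0]])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular KKT system") from None
    return sol  # p_free ++ [lambda]


def deconvolve_qp(
    panel: ReferencePanel | np.ndarray,
    observed,
    marker_subset=None,
    tol: float = KKT_TOL,
    max_iter: int = 200,
) -> TissueProportionEstimate:
    """Estimate tissue proportions for one sample.

    Parameters
    ----------
    panel
        ReferencePanel (or a plain markers x tissues array).
    observed
        Marker methylation vector; NaN entries are dropped pairwise.
    marker_subset
        Optional boolean mask / index array restricting the markers used
        (e.g. one marker class).
    """
    if isinstance(panel, ReferencePanel):
        R = panel.fractions.to_numpy(dtype=float)
        tissues = panel.tissues
    else:
        R = np.asarray(panel, dtype=float)
        tissues = [f"tissue{i}" for i in range(R.shape[1])]
    m = np.asarray(observed, dtype=float).ravel()
    if marker_subset is not None:
        R = R[marker_subset]
        m = m[marker_subset]
    keep = ~np.isnan(m)
    R, m = R[keep], m[keep]
    K, T = R.shape
    if K < T:
        raise ValueError(f"only {K} usable markers for {T} tissues")
    if np.linalg.matrix_rank(R) < T:
        sv = np.linalg.svd(R, compute_uv=False)
        raise ValueError(
            f"rank-deficient reference (singular values {sv.round(6)}): collinear tissues"
        )

    RtR = R.T @ R
    Rtm = R.T @ m
    free = np.ones(T, dtype=bool)
    p = np.full(T, 1.0 / T)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        sol = _solve_kkt(RtR, Rtm, free)
        cand = np.zeros(T)
        cand[free] = sol[:-1]
        lam = sol[-1]
        if cand[free].min() < -tol:
            # step from the last feasible point to the first zero crossing
            delta = cand - p
            neg = free & (delta < 0)
            with np.errstate(divide="ignore"):
                alphas = -p[neg] / delta[neg]
            alpha = float(np.min(alphas))
            p = p + min(1.0, alpha) * delta
            p[~free] = 0.0
            hit = np.flatnonzero(free & (p <= tol))
            # pin the coordinate that actually hit zero (smallest value)
            pin = hit[np.argmin(p[hit])]
            free[pin] = False
            p[pin] = 0.0
            continue
        p = np.where(free, np.maximum(cand, 0.0), 0.0)
        # KKT check for pinned coordinates: gradient - lambda >= 0
        grad = 2.0 * (RtR @ p - Rtm)
        mult = grad - lam
        pinned = np.flatnonzero(~free)
        if len(pinned) and mult[pinned].min() < -tol:
            free[pinned[np.argmin(mult[pinned])]] = True
            continue
        break
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    rss = float(np.sum((R @ p - m) ** 2))
    return TissueProportionEstimate(
        proportions=pd.Series(p, index=tissues),
        rss=rss,
        n_iter=n_iter,
        active_set=tuple(t for t, f in zip(tissues, free) if not f),
    )


def marker_methylation(counts: CpGCountMatrix, panel: ReferencePanel) -> pd.DataFrame:
    """Weighted methylation of each panel marker per sample (NaN where a
    sample has no reads in the marker interval)."""
    chrom_str = counts.chrom.astype(str)
    out = np.full((panel.n_markers, counts.n_samples), np.nan)
    for i, r in enumerate(panel.markers.itertuples(index=False)):
        inside = (chrom_str == r.chrom) & points_in_intervals(counts.pos, [(r.start, r.end)])
        if not inside.any():
            continue
        m = counts.meth[inside].sum(axis=0).astype(float)
        n = counts.total[inside].sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = np.where(n > 0, m / np.maximum(n, 1e-300), np.nan)
    return pd.DataFrame(out, columns=counts.samples)


def compare_proportions(
    estimates: pd.DataFrame, groups: dict[str, str]
) -> pd.DataFrame:
    """Per-tissue two-group comparison of estimated proportions.

    ``estimates`` is samples x tissues. Uses the two-sided Mann-Whitney
    U test — exact null when the combined n is <= 20 and tie-free,
    normal approximation with tie correction otherwise; identical
    constant values in both groups give p = 1. Direction is the sign of
    the group-1 minus group-2 mean.
    """
    labels = []
    for s in estimates.index:
        g = groups[s]
        if g not in labels:
            labels.append(g)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    g1 = [s for s in estimates.index if groups[s] == labels[0]]
    g2 = [s for s in estimates.index if groups[s] == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 samples per group")
    rows = []
    for tissue in estimates.columns:
        x = estimates.loc[g1, tissue].to_numpy(dtype=float)
        y = estimates.loc[g2, tissue].to_numpy(dtype=float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            u, p = len(x) * len(y) / 2.0, 1.0
        else:
            method = "exact" if len(x) + len(y) <= 20 else "asymptotic"
            ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
            if ties:
                method = "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            u, p = float(res.statistic), float(res.pvalue)
        direction = "higher" if x.mean() > y.mean() else ("lower" if x.mean() < y.mean() else "equal")
        rows.append((tissue, u, p, direction))
    df = pd.DataFrame(rows, columns=["tissue", "U", "pvalue", "direction"])
    df["group1"], df["group2"] = labels[0], labels[1]
    return df
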