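"""Per-CpG two-group differential methylation testing.

The model: methylated counts at a CpG are beta-binomial around a
group-level mean that varies smoothly along the genome. Group means are
estimated by coverage-weighted smoothing in a fixed bp window, the
per-site overdispersion phi is estimated by penalized likelihood with a
Gaussian prior on log phi whose location and scale are learned from the
whole genome (shrinkage "borrows information across sites"), and the
difference of group means is tested with a Wald statistic against the
standard normal.

The Wald variance applies the beta-binomial variance of a pooled
proportion to the same window aggregation that produced the smoothed
means, so the statistic is calibrated against the estimator actually
being tested; with window_bp = 0 this reduces to the single-site
formula, and with phi = 0 to the classical two-proportion z-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import CpGCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothedMeans",
    "smooth_means",
    "estimate_dispersion",
    "dml_wald_test",
    "adjust_bh",
    "call_dml",
]

LOG_PHI_BOUNDS = (-8.0, -0.02)
VAR_FLOOR = 1e-8
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class SmoothedMeans:
    """Window-smoothed group means plus the window count aggregates
    needed for the Wald variance.

    ``mu`` is (n_sites, 2) with NaN where a group has zero coverage in
    the window; ``sum_n`` / ``sum_n2`` are the windowed sums of per-sample
    totals and squared totals per group; ``window_bp`` is the full window
    width (the window spans +/- window_bp/2 around each site).
    """

    mu: np.ndarray
    sum_m: np.ndarray
    sum_n: np.ndarray
    sum_n2: np.ndarray
    window_bp: float
    group_names: tuple[str, str]


def _window_bounds(chrom: np.ndarray, pos: np.ndarray, half: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-site [lo, hi) index range of sites within +/- half bp on the
    same chromosome."""
    n = len(pos)
    lo = np.empty(n, dtype=np.int64)
    hi = np.empty(n, dtype=np.int64)
    start = 0
    for c in pd.unique(chrom.astype(str)):
        mask = chrom.astype(str) == c
        idx = np.flatnonzero(mask)
        p = pos[idx]
        lo[idx] = start + np.searchsorted(p, p - half, side="left")
        hi[idx] = start + np.searchsorted(p, p + half, side="right")
        start += len(idx)
    return lo, hi


def _windowed_sum(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    cs = np.concatenate([[0.0], np.cumsum(x)])
    return cs[hi] - cs[lo]


def smooth_means(counts: CpGCountMatrix, window_bp: float = 500.0) -> SmoothedMeans:
    """Coverage-weighted smoothed methylation per group.

    The smoothed mean at site i is sum(M) / sum(N) over all sites within
    +/- window_bp/2 on the same chromosome and all samples of the group;
    window_bp = 0 gives the raw pooled per-site fraction. Sites where a
    group has no coverage anywhere in the window get NaN and are excluded
    from testing.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    g1, g2 = counts.group_labels()[:2]
    cols = [counts.group_columns(g1), counts.group_columns(g2)]
    half = window_bp / 2.0
    lo, hi = _window_bounds(counts.chrom, counts.pos, half)

    n_sites = counts.n_sites
    mu = np.full((n_sites, 2), np.nan)
    sum_m = np.zeros((n_sites, 2))
    sum_n = np.zeros((n_sites, 2))
    sum_n2 = np.zeros((n_sites, 2))
    for g, cc in enumerate(cols):
        m_site = counts.meth[:, cc].sum(axis=1).astype(float)
        n_site = counts.total[:, cc].sum(axis=1).astype(float)
        n2_site = (counts.total[:, cc].astype(float) ** 2).sum(axis=1)
        sum_m[:, g] = _windowed_sum(m_site, lo, hi)
        sum_n[:, g] = _windowed_sum(n_site, lo, hi)
        sum_n2[:, g] = _windowed_sum(n2_site, lo, hi)
        ok = sum_n[:, g] > 0
        mu[ok, g] = sum_m[ok, g] / sum_n[ok, g]
    return SmoothedMeans(mu, sum_m, sum_n, sum_n2, window_bp, (g1, g2))


def _betabinom_loglik(m: np.ndarray, n: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Sum over samples (axis 1) of the beta-binomial log-likelihood with
    shape (mu(1-phi)/phi, (1-mu)(1-phi)/phi); combinatorial terms dropped
    (constant in phi)."""
    a = mu * (1.0 - phi) / phi
    b = (1.0 - mu) * (1.0 - phi) / phi
    ll = (
        special.betaln(m + a, n - m + b)
        - special.betaln(a, b)
    )
    ll = np.where(n > 0, ll, 0.0)
    return ll.sum(axis=1)


def estimate_dispersion(
    counts: CpGCountMatrix,
    smoothed: SmoothedMeans,
    prior_weight: float = 1.0,
    log_phi_bounds: tuple[float, float] = LOG_PHI_BOUNDS,
    tol: float = 1e-6,
) -> np.ndarray:
    """Shrunken per-site beta-binomial dispersion.

    Per site, phi maximizes the beta-binomial log-likelihood of all
    samples (group means fixed at their smoothed values) minus the
    penalty ``prior_weight * (log phi - m0)^2 / (2 s0^2)``, where m0 and
    s0 are the mean and sd of the log method-of-moments estimates over
    all usable sites (s0 floored at 0.5). The optimum is located by
    golden-section search on log phi, vectorized over sites.

    Sites with at most one covered sample get ``exp(m0)`` directly.
    """
    g1, g2 = smoothed.group_names
    cols1 = counts.group_columns(g1)
    cols2 = counts.group_columns(g2)
    order = np.concatenate([cols1, cols2])
    M = counts.meth[:, order].astype(float)
    N = counts.total[:, order].astype(float)
    n_sites, n_samp = M.shape

    # per-sample group mean, clipped away from {0, 1} for the likelihood
    mu_site = np.column_stack(
        [np.repeat(smoothed.mu[:, 0:1], len(cols1), axis=1),
         np.repeat(smoothed.mu[:, 1:2], len(cols2), axis=1)]
    )
    mu_site = np.clip(mu_site, 1e-4, 1 - 1e-4)
    usable = (N > 0) & ~np.isnan(mu_site)
    mu_site = np.where(usable, mu_site, 0.5)
    N_eff = np.where(usable, N, 0.0)
    M_eff = np.where(usable, M, 0.0)
    n_covered = usable.sum(axis=1)

    # method-of-moments site estimates -> prior location/scale
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(N_eff > 0, M_eff / np.maximum(N_eff, 1), np.nan)
        resid2 = (p_hat - mu_site) ** 2
        v = mu_site * (1 - mu_site)
        num = np.nansum(np.where(usable, resid2 - v / np.maximum(N_eff, 1), np.nan), axis=1)
        den = np.nansum(np.where(usable, v * (1 - 1 / np.maximum(N_eff, 1)), np.nan), axis=1)
    lo_b, hi_b = log_phi_bounds
    mom = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    good = (n_covered >= 2) & np.isfinite(mom) & (mom > 0)
    mom = np.clip(mom, np.exp(lo_b), np.exp(hi_b))
    if good.sum() == 0:
        m0, s0 = np.log(0.01), 0.5
    else:
        logs = np.log(mom[good])
        m0 = float(np.mean(logs))
        s0 = max(float(np.std(logs)), 0.5)

    phi_out = np.full(n_sites, np.exp(m0))
    active = n_covered >= 2
    if prior_weight == np.inf or not active.any():
        return phi_out

    Ma, Na, mua = M_eff[active], N_eff[active], mu_site[active]

    def objective(log_phi: np.ndarray) -> np.ndarray:
        phi = np.exp(log_phi)
        ll = _betabinom_loglik(Ma, Na, mua, phi[:, None])
        return ll - prior_weight * (log_phi - m0) ** 2 / (2.0 * s0**2)

    # golden-section search on log phi, elementwise over active sites;
    # one objective evaluation per site per iteration
    a = np.full(active.sum(), lo_b)
    b = np.full(active.sum(), hi_b)
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc = objective(c)
    fd = objective(d)
    while np.max(b - a) > tol:
        go_left = fc > fd  # maximum lies in [a, d]
        b = np.where(go_left, d, b)
        a = np.where(go_left, a, c)
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        # for left moves the old c becomes the new d (and vice versa), so
        # only the outer probe point needs a fresh evaluation
        x = np.where(go_left, c, d)
        fx = objective(x)
        fc, fd = np.where(go_left, fx, fd), np.where(go_left, fc, fx)
    phi_out[active] = np.exp((a + b) / 2.0)
    return phi_out


def dml_wald_test(
    counts: CpGCountMatrix,
    smoothed: SmoothedMeans,
    dispersions: np.ndarray,
) -> pd.DataFrame:
    """Wald test of the smoothed group-mean difference at every CpG.

    For group g the variance of the pooled windowed proportion is
    ``mu(1-mu) * [(1-phi) * sum(N) + phi * sum(N^2)] / sum(N)^2`` (the
    beta-binomial variance of a coverage-weighted mean); the statistic is
    ``W = (mu1 - mu2) / sqrt(Var1 + Var2)`` with a two-sided normal
    p-value. Sites covered in only one group are excluded (logged); an
    exactly 0 or 1 smoothed mean triggers the variance floor.

    Returns a frame with columns chrom, pos, mu1, mu2, diff, se, stat,
    pval, fdr, phi, n_total (total reads across samples, used for
    coverage-weighted region summaries).
    """
    mu = smoothed.mu
    ok = ~np.isnan(mu).any(axis=1) & (smoothed.sum_n > 0).all(axis=1)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("excluding %d sites covered in only one group", n_excluded)

    phi = np.asarray(dispersions, dtype=float)
    var = np.empty((counts.n_sites, 2))
    for g in range(2):
        v = mu[:, g] * (1 - mu[:, g])
        sn, sn2 = smoothed.sum_n[:, g], smoothed.sum_n2[:, g]
        with np.errstate(invalid="ignore", divide="ignore"):
            var[:, g] = v * ((1 - phi) * sn + phi * sn2) / sn**2
    var = np.maximum(var, VAR_FLOOR)

    diff = mu[:, 0] - mu[:, 1]
    se = np.sqrt(var[:, 0] + var[:, 1])
    stat = diff / se
    pval = 2.0 * stats.norm.sf(np.abs(stat))

    df = pd.DataFrame(
        {
            "chrom": counts.chrom.astype(str),
            "pos": counts.pos,
            "mu1": mu[:, 0],
            "mu2": mu[:, 1],
            "diff": diff,
            "se": se,
            "stat": stat,
            "pval": pval,
            "phi": phi,
            "n_total": counts.total.sum(axis=1),
        }
    )
    df = df[ok].reset_index(drop=True)
    df["fdr"] = adjust_bh(df["pval"].to_numpy())
    return df[["chrom", "pos", "mu1", "mu2", "diff", "se", "stat", "pval", "fdr", "phi", "n_total"]]


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dml(records: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Significant differentially methylated loci: FDR < threshold."""
    return records[records["fdr"] < fdr_threshold].reset_index(drop=True)


def test_dml(counts: CpGCountMatrix, window_bp: float = 500.0,
             prior_weight: float = 1.0) -> pd.DataFrame:
    """Convenience wrapper: smoothing, dispersion shrinkage, Wald test."""
    sm = smooth_means(counts, window_bp=window_bp)
    phi = estimate_dispersion(counts, sm, prior_weight=prior_weight)
    return dml_wald_test(counts, sm, phi)
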