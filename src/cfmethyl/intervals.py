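"""Half-open interval arithmetic on a single chromosome.

All intervals are 0-based half-open [start, end) and represented as an
(n, 2) int64 array. These primitives back annotation overlap queries,
genomic-space accounting for enrichment, and the synthetic annotation
builder.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_interval_array",
    "merge_intervals",
    "subtract_intervals",
    "complement_intervals",
    "total_length",
    "points_in_intervals",
    "intervals_overlapping",
    "distance_to_intervals",
]


def as_interval_array(iv) -> np.ndarray:
    arr = np.asarray(iv, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be an (n, 2) array")
    if np.any(arr[:, 0] >= arr[:, 1]):
        raise ValueError("interval start must be < end")
    return arr


def merge_intervals(iv) -> np.ndarray:
    """Sort and merge overlapping or bookended intervals."""
    arr = as_interval_array(iv)
    if len(arr) == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [arr[0].copy()]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out, dtype=np.int64)


def subtract_intervals(iv, minus) -> np.ndarray:
    """Set difference iv \\ minus; both merged internally."""
    a = merge_intervals(iv)
    b = merge_intervals(minus)
    if len(a) == 0 or len(b) == 0:
        return a
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def complement_intervals(iv, length: int) -> np.ndarray:
    """Complement within [0, length)."""
    return subtract_intervals([(0, int(length))], iv)


def total_length(iv) -> int:
    arr = merge_intervals(iv)
    if len(arr) == 0:
        return 0
    return int(np.sum(arr[:, 1] - arr[:, 0]))


def points_in_intervals(points, iv) -> np.ndarray:
    """Boolean mask: is each point inside some interval (merged first)."""
    arr = merge_intervals(iv)
    pts = np.asarray(points, dtype=np.int64)
    if len(arr) == 0:
        return np.zeros(pts.shape, dtype=bool)
    idx = np.searchsorted(arr[:, 0], pts, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(pts.shape, dtype=bool)
    inside[ok] = pts[ok] < arr[idx[ok], 1]
    return inside


def intervals_overlapping(query, iv) -> np.ndarray:
    """Boolean mask: does each query interval overlap >=1 bp of iv."""
    arr = merge_intervals(iv)
    q = as_interval_array(query)
    if len(arr) == 0 or len(q) == 0:
        return np.zeros(len(q), dtype=bool)
    # first merged interval ending after query start
    lo = np.searchsorted(arr[:, 1], q[:, 0], side="right")
    hit = lo < len(arr)
    out = np.zeros(len(q), dtype=bool)
    out[hit] = arr[lo[hit], 0] < q[hit, 1]
    return out


def distance_to_intervals(points, iv) -> np.ndarray:
    """bp distance from each point to the nearest interval (0 if inside)."""
    arr = merge_intervals(iv)
    pts = np.asarray(points, dtype=np.int64)
    if len(arr) == 0:
        return np.full(pts.shape, np.iinfo(np.int64).max, dtype=np.int64)
    inside = points_in_intervals(pts, arr)
    # gap to previous end and next start; ends are exclusive so the last
    # covered base of [s, e) is e-1
    nxt = np.searchsorted(arr[:, 0], pts, side="left")
    d_next = np.where(nxt < len(arr), arr[np.minimum(nxt, len(arr) - 1), 0] - pts, np.iinfo(np.int64).max)
    prv = nxt - 1
    d_prev = np.where(prv >= 0, pts - (arr[np.maximum(prv, 0), 1] - 1), np.iinfo(np.int64).max)
    dist = np.minimum(np.maximum(d_next, 0), np.maximum(d_prev, 0))
    dist[inside] = 0
    return dist
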