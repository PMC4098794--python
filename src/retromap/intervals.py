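"""Half-open genomic interval arithmetic.

All intervals are 0-based half-open ``(start, end)`` tuples, BED-style.
Interval lists are plain Python lists (small) with numpy used for point
membership queries, which is the hot path in the enrichment statistics.
"""

from __future__ import annotations

import numpy as np

Interval = tuple[int, int]


def validate_intervals(intervals: list[Interval]) -> None:
    for s, e in intervals:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping or touching intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def pad_intervals(
    intervals: list[Interval], pad: int, lo: int = 0, hi: int | None = None
) -> list[Interval]:
    """Extend every interval by ``pad`` on both sides, clip to [lo, hi), merge."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    out = []
    for s, e in intervals:
        s2 = max(lo, s - pad)
        e2 = e + pad if hi is None else min(hi, e + pad)
        if e2 > s2:
            out.append((s2, e2))
    return merge_intervals(out)


def total_length(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def points_in_intervals(points: np.ndarray, intervals: list[Interval]) -> np.ndarray:
    """Boolean mask: which points fall inside the merged intervals."""
    points = np.asarray(points, dtype=np.int64)
    if not intervals:
        return np.zeros(points.shape, dtype=bool)
    merged = merge_intervals(intervals)
    starts = np.array([s for s, _ in merged], dtype=np.int64)
    ends = np.array([e for _, e in merged], dtype=np.int64)
    idx = np.searchsorted(starts, points, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(points.shape, dtype=bool)
    inside[ok] = points[ok] < ends[idx[ok]]
    return inside


def intersect_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Intersection of two interval lists (each merged internally first)."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_intervals(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Parts of ``a`` not covered by ``b``."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def nearest_distance(points: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Absolute distance from each point to the nearest site (sites sorted)."""
    points = np.asarray(points, dtype=np.int64)
    sites = np.sort(np.asarray(sites, dtype=np.int64))
    if sites.size == 0:
        return np.full(points.shape, np.inf)
    idx = np.searchsorted(sites, points)
    left = np.clip(idx - 1, 0, sites.size - 1)
    right = np.clip(idx, 0, sites.size - 1)
    d = np.minimum(np.abs(points - sites[left]), np.abs(points - sites[right]))
    return d.astype(float)
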