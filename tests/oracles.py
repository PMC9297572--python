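"""Independent brute-force oracles used to validate the fast implementations.

Everything here works on per-base boolean arrays or exhaustive dynamic
programming / enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def mask_array(intervals, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base boolean occupancy per chromosome."""
    arrays = {c: np.zeros(l, dtype=bool) for c, l in chrom_lengths.items()}
    for iv in intervals:
        arrays[iv.chrom][iv.start : iv.end] = True
    return arrays


def masked_bases(intervals, chrom_lengths) -> int:
    return sum(int(a.sum()) for a in mask_array(intervals, chrom_lengths).values())


def intersect_bases(a, b, chrom_lengths) -> int:
    ma, mb = mask_array(a, chrom_lengths), mask_array(b, chrom_lengths)
    return sum(int((ma[c] & mb[c]).sum()) for c in chrom_lengths)


def covered_fraction(target, mask, chrom_lengths) -> float:
    arr = mask_array(mask, chrom_lengths)[target.chrom]
    return float(arr[target.start : target.end].sum()) / (target.end - target.start)


def merged_from_array(arrays: dict[str, np.ndarray]):
    """Disjoint (chrom, start, end) runs of True, sorted by chrom then start."""
    out = []
    for chrom in sorted(arrays):
        a = arrays[chrom]
        padded = np.concatenate(([False], a, [False])).astype(np.int8)
        d = np.diff(padded)
        starts, ends = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def window_hit_counts(intervals, chrom_lengths, window: int) -> int:
    """Number of windows containing >= 1 masked base (any-overlap rule)."""
    n = 0
    arrays = mask_array(intervals, chrom_lengths)
    for chrom, length in chrom_lengths.items():
        a = arrays[chrom]
        for start in range(0, length, window):
            if a[start : start + window].any():
                n += 1
    return n


def complete_linkage(names: list[str], columns: np.ndarray):
    """Exhaustive O(n^3) complete-linkage agglomeration on Euclidean distances.

    ``columns`` has one row per name.  Returns merge events
    (members_a, members_b, height) with the pair of minimal complete-linkage
    distance merged at each step (ties by sorted member names).
    """
    clusters = [frozenset({n}) for n in names]
    vec = {n: columns[i].astype(float) for i, n in enumerate(names)}

    def dist(ca, cb):
        return max(
            float(np.linalg.norm(vec[x] - vec[y])) for x in ca for y in cb
        )

    events = []
    while len(clusters) > 1:
        best = None
        for ca, cb in itertools.combinations(clusters, 2):
            d = dist(ca, cb)
            key = (d, tuple(sorted(ca | cb)))
            if best is None or key < best[0]:
                best = (key, ca, cb)
        _, ca, cb = best
        if sorted(cb) < sorted(ca):
            ca, cb = cb, ca
        events.append((ca, cb, best[0][0]))
        clusters = [c for c in clusters if c not in (ca, cb)] + [ca | cb]
    return events


def lcs_length(a: list[str], b: list[str]) -> int:
    """Quadratic DP longest-common-subsequence length."""
    dp = np.zeros((len(a) + 1, len(b) + 1), dtype=int)
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            dp[i + 1, j + 1] = (
                dp[i, j] + 1 if x == y else max(dp[i, j + 1], dp[i + 1, j])
            )
    return int(dp[-1, -1])


def max_hit_index(row: np.ndarray) -> int:
    """Exhaustive scan: largest 1-based index with a hit, 0 when none."""
    out = 0
    for i, v in enumerate(row, 1):
        if v:
            out = i
    return out
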