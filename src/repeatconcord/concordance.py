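"""Multi-tool repeat-mask comparison.

A genome is tiled in fixed windows (1 kb in the study design this module
supports); each annotation tool contributes a 0/1 column saying whether a
window contains any masked base.  On this presence matrix the module provides
complete-linkage hierarchical clustering of tools (Euclidean distance between
binary columns), most-abundant presence/absence pattern counts, base-level
pairwise agreement against a reference tool, and per-tool coverage summaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .genomic_intervals import (
    RepeatAnnotationSet,
    ValidationError,
    WindowGrid,
    intersect_length,
    total_masked_bases,
    window_coverage_bases,
)

__all__ = [
    "PresenceMatrix",
    "PatternCount",
    "MethodDendrogram",
    "binarize_windows",
    "cluster_methods",
    "pattern_abundance",
    "pairwise_agreement",
    "coverage_summary",
]


@dataclass
class PresenceMatrix:
    """window x method 0/1 matrix on a :class:`WindowGrid`."""

    grid: WindowGrid
    methods: tuple[str, ...]
    values: np.ndarray  # shape (n_windows, n_methods), int8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (self.grid.n_windows, len(self.methods)):
            raise ValueError(
                f"presence matrix shape {self.values.shape} does not match "
                f"{self.grid.n_windows} windows x {len(self.methods)} methods"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0/1")

    def column(self, method: str) -> np.ndarray:
        return self.values[:, self.methods.index(method)]


@dataclass(frozen=True)
class PatternCount:
    pattern: tuple[int, ...]
    count: int


@dataclass
class MethodDendrogram:
    """Complete-linkage merge sequence over methods.

    ``merge_events`` lists (members_a, members_b, height) in merge order;
    heights are Euclidean distances and non-decreasing (complete linkage is
    monotone).  Methods are canonicalized to lexicographic order before
    clustering so the result is invariant to input order.
    """

    methods: tuple[str, ...]  # lexicographically sorted leaf order
    linkage_matrix: np.ndarray  # scipy linkage format
    merge_events: tuple[tuple[frozenset[str], frozenset[str], float], ...]

    def first_merge_partners(self, method: str) -> frozenset[str]:
        """Members of the cluster a method is first merged with."""
        for a, b, _ in self.merge_events:
            if method in a:
                return b
            if method in b:
                return a
        raise KeyError(method)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "members_a": ",".join(sorted(a)),
                "members_b": ",".join(sorted(b)),
                "height": h,
            }
            for a, b, h in self.merge_events
        ]
        return pd.DataFrame(rows, columns=["members_a", "members_b", "height"])


def binarize_windows(
    sets: list[RepeatAnnotationSet],
    grid: WindowGrid,
    min_bases: int = 1,
) -> PresenceMatrix:
    """Build the window x method presence matrix.

    A window scores 1 for a method when at least ``min_bases`` of it are masked
    (default 1: any overlap, including elements spanning window boundaries).
    """
    if min_bases < 1:
        raise ValueError("min_bases must be >= 1")
    for aset in sets:
        if aset.index is not None and aset.index != grid.index:
            raise ValidationError(
                f"annotation set {aset.source!r} is bound to a different genome "
                "index than the window grid"
            )
    cols = []
    for aset in sets:
        bases = window_coverage_bases(aset.intervals(), grid)
        cols.append((bases >= min_bases).astype(np.int8))
    values = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((grid.n_windows, 0), dtype=np.int8)
    )
    return PresenceMatrix(
        grid=grid, methods=tuple(s.source for s in sets), values=values
    )


def cluster_methods(pm: PresenceMatrix) -> MethodDendrogram:
    """Agglomerative complete-linkage clustering of method columns (Euclidean).

    Deterministic: methods are sorted lexicographically before linkage, which
    also makes the dendrogram invariant under permutation of the input sets.
    """
    if len(pm.methods) < 2:
        raise ValueError("clustering requires >= 2 methods")
    order = sorted(range(len(pm.methods)), key=lambda i: pm.methods[i])
    methods = tuple(pm.methods[i] for i in order)
    X = pm.values[:, order].T.astype(float)
    Z = linkage(X, method="complete", metric="euclidean")
    clusters: dict[int, frozenset[str]] = {
        i: frozenset({m}) for i, m in enumerate(methods)
    }
    events = []
    n = len(methods)
    for k, (ia, ib, height, _) in enumerate(Z):
        a, b = clusters[int(ia)], clusters[int(ib)]
        # canonical orientation: lexicographically smaller member set first
        if sorted(b) < sorted(a):
            a, b = b, a
        events.append((a, b, float(height)))
        clusters[n + k] = a | b
    return MethodDendrogram(
        methods=methods, linkage_matrix=Z, merge_events=tuple(events)
    )


def pattern_abundance(pm: PresenceMatrix, top_k: int = 20) -> list[PatternCount]:
    """The ``top_k`` most frequent nonzero presence/absence row patterns.

    Sorted by count descending, ties by lexicographic pattern order; the
    all-zero pattern (windows no tool masked) is excluded.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    counts = Counter(map(tuple, pm.values.tolist()))
    counts.pop((0,) * len(pm.methods), None)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [PatternCount(pattern=p, count=c) for p, c in ranked[:top_k]]


def pairwise_agreement(
    a: RepeatAnnotationSet,
    reference: RepeatAnnotationSet,
    mode: str = "base",
    grid: WindowGrid | None = None,
) -> float:
    """Fraction of method ``a``'s mask also covered by ``reference``.

    Asymmetric by design: the denominator is the compared method's own mask, so
    a tool whose calls are a subset of the reference scores 1.0.  ``mode='base'``
    (default) works at base level; ``mode='window'`` compares window presence on
    ``grid`` instead.
    """
    if mode == "base":
        denom = total_masked_bases(a)
        if denom == 0:
            raise ValueError(
                f"pairwise agreement undefined: {a.source!r} masks no bases"
            )
        return intersect_length(a.intervals(), reference.intervals()) / denom
    if mode == "window":
        if grid is None:
            raise ValueError("window-level agreement requires a WindowGrid")
        pm = binarize_windows([a, reference], grid)
        col_a, col_r = pm.values[:, 0].astype(bool), pm.values[:, 1].astype(bool)
        denom = int(col_a.sum())
        if denom == 0:
            raise ValueError(
                f"pairwise agreement undefined: {a.source!r} hits no windows"
            )
        return int((col_a & col_r).sum()) / denom
    raise ValueError(f"unknown agreement mode {mode!r}")


def coverage_summary(sets: list[RepeatAnnotationSet]) -> pd.DataFrame:
    """Per-method merged masked bases and genome fraction.

    Requires every set to be bound to the same genome index (the fraction
    denominator).
    """
    indexes = {id(s.index): s.index for s in sets if s.index is not None}
    if len({tuple(ix.entries) for ix in indexes.values()}) != 1:
        raise ValidationError("coverage summary requires one common genome index")
    genome_len = next(iter(indexes.values())).total_length
    rows = []
    for s in sets:
        bp = total_masked_bases(s)
        rows.append(
            {"method": s.source, "masked_bp": bp, "genome_fraction": bp / genome_len}
        )
    return pd.DataFrame(rows, columns=["method", "masked_bp", "genome_fraction"])
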