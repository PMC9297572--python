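"""Gene-order synteny alignment and lineage-specific insertion detection.

Each species' scaffolds are ordered sequences of ortholog-family tokens.
Families occurring exactly once on both scaffolds act as anchors; the
alignment is the longest common subsequence of anchor tokens, tried in both
orientations (forward and reversed outgroup scaffold) with the better chain
kept.  Because anchors are single-copy on both sides, the LCS reduces to a
longest increasing subsequence over matched positions and is computed in
O(n log n) with patience sorting.

An insertion call is made for a run of focal genes from the target families
sitting between two anchors that are consecutive in the chains against BOTH
outgroups (with at most ``max_gap`` intervening non-anchor, non-target genes
in the focal order), while no target-family gene lies between the matched
anchors in either outgroup — i.e. the outgroups retain the ancestral,
uninterrupted block.
"""

from __future__ import annotations

import bisect
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UNASSIGNED",
    "GeneOrder",
    "AnchorPair",
    "InsertionCall",
    "align_gene_orders",
    "detect_lineage_specific_insertions",
    "read_gene_order",
    "write_gene_order",
]

UNASSIGNED = "UNASSIGNED"


@dataclass
class GeneOrder:
    """Per-species gene order: scaffold -> ordered (gene_id, family) pairs."""

    species: str
    scaffolds: dict[str, list[tuple[str, str]]]

    def __post_init__(self) -> None:
        gene_ids = [g for genes in self.scaffolds.values() for g, _ in genes]
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError(f"duplicate gene ids in species {self.species}")

    def families(self, scaffold: str) -> list[str]:
        return [fam for _, fam in self.scaffolds[scaffold]]


@dataclass(frozen=True)
class AnchorPair:
    family: str
    pos_a: int  # index in species-a scaffold order
    pos_b: int  # index in species-b scaffold order


@dataclass(frozen=True)
class InsertionCall:
    scaffold: str
    gene_ids: tuple[str, ...]
    family: str
    left_anchor: str
    right_anchor: str
    supported_by: frozenset[str]


def _single_copy(families: list[str]) -> set[str]:
    counts = Counter(families)
    return {f for f, n in counts.items() if n == 1 and f != UNASSIGNED}


def _lis_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest strictly-increasing-in-second-coordinate subsequence of pairs
    already sorted by first coordinate (patience sorting with backtracking)."""
    tails: list[int] = []  # tails[k] = index into pairs of best end of length k+1
    tail_vals: list[int] = []
    prev = [-1] * len(pairs)
    for i, (_, b) in enumerate(pairs):
        k = bisect.bisect_left(tail_vals, b)
        if k == len(tail_vals):
            tail_vals.append(b)
            tails.append(i)
        else:
            tail_vals[k] = b
            tails[k] = i
        prev[i] = tails[k - 1] if k > 0 else -1
    if not tails:
        return []
    chain = []
    i = tails[-1]
    while i >= 0:
        chain.append(pairs[i])
        i = prev[i]
    return chain[::-1]


def align_gene_orders(
    a: GeneOrder, b: GeneOrder, scaffold_a: str, scaffold_b: str
) -> list[AnchorPair]:
    """Anchor chain between two scaffolds: LCS over single-copy family tokens.

    Both orientations of the ``b`` scaffold are tried and the longer chain
    kept (tie -> forward).  Returned pairs are in increasing ``pos_a`` order;
    ``pos_b`` is monotone increasing (forward) or decreasing (reversed).
    """
    fams_a, fams_b = a.families(scaffold_a), b.families(scaffold_b)
    if not fams_a or not fams_b:
        raise ValueError("cannot align empty scaffolds")
    anchors = _single_copy(fams_a) & _single_copy(fams_b)
    pos_b = {f: i for i, f in enumerate(fams_b) if f in anchors}
    pairs = [(i, pos_b[f]) for i, f in enumerate(fams_a) if f in anchors]
    forward = _lis_chain(pairs)
    reverse = _lis_chain([(i, -j) for i, j in pairs])
    best = forward if len(forward) >= len(reverse) else [(i, -j) for i, j in reverse]
    return [AnchorPair(family=fams_a[i], pos_a=i, pos_b=j) for i, j in best]


def _best_scaffold_chain(
    focal: GeneOrder, scaffold: str, other: GeneOrder
) -> tuple[str, list[AnchorPair]] | None:
    """Outgroup scaffold giving the longest anchor chain against a focal
    scaffold (ties -> lexicographically first scaffold name)."""
    best: tuple[str, list[AnchorPair]] | None = None
    for sc in sorted(other.scaffolds):
        if not other.scaffolds[sc] or not focal.scaffolds[scaffold]:
            continue
        chain = align_gene_orders(focal, other, scaffold, sc)
        if best is None or len(chain) > len(best[1]):
            best = (sc, chain)
    return best


def detect_lineage_specific_insertions(
    focal: GeneOrder,
    out1: GeneOrder,
    out2: GeneOrder,
    target_families: set[str],
    max_gap: int = 2,
) -> list[InsertionCall]:
    """Focal-lineage-specific insertions of ``target_families`` genes.

    For every focal scaffold, anchor chains against each outgroup are built on
    the best-matching outgroup scaffold.  For each maximal run of target-family
    genes in the focal order, and for each outgroup independently, the nearest
    chain anchors flanking the run are located; a call requires, in BOTH
    outgroups: (i) flanking anchors exist on both sides, (ii) at most
    ``max_gap`` focal genes between those anchors are neither targets nor
    anchors, and (iii) no target-family gene lies between the matched anchor
    positions in the outgroup (the outgroups retain the uninterrupted block).
    Reported anchors are those of the first outgroup's chain.  Scaffolds with
    fewer than two anchors against either outgroup are skipped with a warning.
    """
    calls: list[InsertionCall] = []
    for scaffold in sorted(focal.scaffolds):
        genes = focal.scaffolds[scaffold]
        if not genes:
            continue
        chains: dict[str, tuple[GeneOrder, str, list[AnchorPair]]] = {}
        skip = False
        for other in (out1, out2):
            best = _best_scaffold_chain(focal, scaffold, other)
            if best is None or len(best[1]) < 2:
                logger.warning(
                    "scaffold %s: fewer than 2 anchors against %s; skipped",
                    scaffold,
                    other.species,
                )
                skip = True
                break
            chains[other.species] = (other, *best)
        if skip:
            continue
        # maximal runs of target-family genes in the focal order
        runs: list[tuple[int, int]] = []
        i = 0
        while i < len(genes):
            if genes[i][1] in target_families:
                j = i
                while j + 1 < len(genes) and genes[j + 1][1] in target_families:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        for i0, i1 in runs:
            supported = True
            report_anchors: tuple[str, str] | None = None
            for sp in (out1.species, out2.species):
                other, sc, chain = chains[sp]
                left = next(
                    (p for p in reversed(chain) if p.pos_a < i0), None
                )
                right = next((p for p in chain if p.pos_a > i1), None)
                if left is None or right is None:
                    supported = False
                    break
                between = genes[left.pos_a + 1 : right.pos_a]
                n_plain = sum(1 for _, f in between if f not in target_families)
                if n_plain > max_gap:
                    supported = False
                    break
                lo, hi = sorted((left.pos_b, right.pos_b))
                if any(
                    f in target_families
                    for _, f in other.scaffolds[sc][lo + 1 : hi]
                ):
                    supported = False
                    break
                if report_anchors is None:
                    report_anchors = (left.family, right.family)
            if not supported:
                continue
            run_genes = genes[i0 : i1 + 1]
            assert report_anchors is not None
            for family in sorted({f for _, f in run_genes}):
                calls.append(
                    InsertionCall(
                        scaffold=scaffold,
                        gene_ids=tuple(g for g, f in run_genes if f == family),
                        family=family,
                        left_anchor=report_anchors[0],
                        right_anchor=report_anchors[1],
                        supported_by=frozenset({out1.species, out2.species}),
                    )
                )
    return calls


def read_gene_order(path: str | Path, species: str | None = None) -> GeneOrder:
    """Read a per-species TSV (scaffold, position, gene_id, family); rows are
    sorted by position within each scaffold."""
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "gene_id": str, "family": str})
    required = {"scaffold", "position", "gene_id", "family"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene order TSV needs columns {sorted(required)}")
    scaffolds: dict[str, list[tuple[str, str]]] = {}
    for sc, sub in df.groupby("scaffold", sort=True):
        sub = sub.sort_values("position")
        scaffolds[str(sc)] = list(zip(sub["gene_id"], sub["family"]))
    return GeneOrder(species=species or Path(path).stem, scaffolds=scaffolds)


def write_gene_order(order: GeneOrder, path: str | Path) -> None:
    rows = [
        {"scaffold": sc, "position": i, "gene_id": g, "family": f}
        for sc in sorted(order.scaffolds)
        for i, (g, f) in enumerate(order.scaffolds[sc])
    ]
    pd.DataFrame(rows, columns=["scaffold", "position", "gene_id", "family"]).to_csv(
        path, sep="\t", index=False
    )
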