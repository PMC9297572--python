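"""Repeat-gene overlap analyses.

Two complementary screens, mirroring how transcriptional evidence for active
transposons is usually gathered:

* full containment — a single-exon transcript whose exon lies entirely inside
  the (per-class merged) repeat mask is a candidate actively transcribed TE;
* fractional coverage — for annotated multi-isoform genes, isoforms are merged
  into one non-redundant exon set and an exon counts as repeat-associated when
  at least ``min_frac`` (default 50%, inclusive) of its bases are masked.

Superfamily attribution goes to the raw element with the largest overlap
(ties broken lexicographically; all tied superfamilies retained in a secondary
field).  A tally with a minimum-transcript cutoff (default 20) surfaces the
superfamilies with the broadest transcriptional support.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .genomic_intervals import (
    Interval,
    RepeatAnnotationSet,
    RepeatElement,
    TEClass,
    intersect_length,
    merge_intervals,
)

__all__ = [
    "Transcript",
    "GeneModel",
    "OverlapRecord",
    "merge_isoforms",
    "fully_contained_overlaps",
    "exon_coverage_overlaps",
    "superfamily_tally",
    "gene_class_map",
    "records_to_frame",
]


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[Interval, ...]
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons unsorted or overlapping"
                )

    @property
    def is_single_exon(self) -> bool:
        return len(self.exons) == 1


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")


@dataclass(frozen=True)
class OverlapRecord:
    """One qualifying (exon, TE class) overlap."""

    gene_id: str
    transcript_id: str
    exon: Interval
    te_class: TEClass
    superfamily: str
    covered_fraction: float
    tied_superfamilies: tuple[str, ...] = field(default_factory=tuple)


def merge_isoforms(genes: list[GeneModel]) -> list[GeneModel]:
    """Collapse each gene to one synthetic transcript whose exons are the merged
    union of all isoform exons (the non-redundant exon set)."""
    out = []
    for gene in genes:
        exons = merge_intervals(e for t in gene.transcripts for e in t.exons)
        strand = gene.transcripts[0].strand
        out.append(
            GeneModel(
                gene_id=gene.gene_id,
                transcripts=(
                    Transcript(
                        transcript_id=f"{gene.gene_id}.merged",
                        exons=tuple(exons),
                        strand=strand,
                    ),
                ),
            )
        )
    return out


def _class_trees(aset: RepeatAnnotationSet) -> dict[TEClass, dict[str, IntervalTree]]:
    """Per-class, per-chrom interval trees over raw elements, for attribution."""
    trees: dict[TEClass, dict[str, IntervalTree]] = {}
    for el in aset.elements:
        trees.setdefault(el.te_class, {}).setdefault(
            el.interval.chrom, IntervalTree()
        ).addi(el.interval.start, el.interval.end, el)
    return trees


def _attribute_superfamily(
    exon: Interval,
    trees: dict[str, IntervalTree],
) -> tuple[str, tuple[str, ...]]:
    """Superfamily of the raw element with the largest overlap with the exon.

    Ties go to the lexicographically first superfamily; all maximal
    superfamilies are returned as the secondary field.
    """
    overlaps: dict[str, int] = {}  # superfamily -> best single-element overlap
    tree = trees.get(exon.chrom)
    if tree is not None:
        for hit in tree.overlap(exon.start, exon.end):
            el: RepeatElement = hit.data
            ol = min(exon.end, el.interval.end) - max(exon.start, el.interval.start)
            sf = el.superfamily
            overlaps[sf] = max(overlaps.get(sf, 0), ol)
    if not overlaps:
        return "", ()
    best = max(overlaps.values())
    tied = tuple(sorted(sf for sf, ol in overlaps.items() if ol == best))
    return tied[0], tied


def fully_contained_overlaps(
    se_transcripts: list[GeneModel],
    aset: RepeatAnnotationSet,
    raw_elements: bool = False,
) -> list[OverlapRecord]:
    """Single-exon transcripts whose exon is fully inside the repeat mask.

    By default containment is tested against the merged per-class mask, so a
    single element fragmented by the annotator still counts; ``raw_elements``
    instead requires containment within one raw element (BEDTools
    ``intersect -f 1``-style).  Multi-exon input is rejected.
    """
    for gene in se_transcripts:
        for t in gene.transcripts:
            if not t.is_single_exon:
                raise ValueError(
                    f"transcript {t.transcript_id} of gene {gene.gene_id} has "
                    f"{len(t.exons)} exons; full-containment analysis takes "
                    "single-exon transcripts only"
                )
    trees = _class_trees(aset)
    merged = {cls: aset.merged(cls) for cls in aset.te_classes}
    records: list[OverlapRecord] = []
    for gene in se_transcripts:
        for t in gene.transcripts:
            exon = t.exons[0]
            for cls in aset.te_classes:
                if raw_elements:
                    tree = trees[cls].get(exon.chrom)
                    contained = tree is not None and any(
                        hit.begin <= exon.start and hit.end >= exon.end
                        for hit in tree.overlap(exon.start, exon.end)
                    )
                else:
                    contained = (
                        intersect_length([exon], merged[cls]) == exon.length
                    )
                if not contained:
                    continue
                sf, tied = _attribute_superfamily(exon, trees[cls])
                records.append(
                    OverlapRecord(
                        gene_id=gene.gene_id,
                        transcript_id=t.transcript_id,
                        exon=exon,
                        te_class=cls,
                        superfamily=sf,
                        covered_fraction=1.0,
                        tied_superfamilies=tied,
                    )
                )
    return records


def exon_coverage_overlaps(
    genes: list[GeneModel],
    aset: RepeatAnnotationSet,
    min_frac: float = 0.5,
) -> list[OverlapRecord]:
    """Exons covered by a repeat class at >= ``min_frac`` of their length.

    ``genes`` is expected to be isoform-merged (see :func:`merge_isoforms`).
    The threshold is inclusive ("at least").  A gene counts as overlapping
    when any exon qualifies for any class.
    """
    if not (0 < min_frac <= 1):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    trees = _class_trees(aset)
    merged = {cls: aset.merged(cls) for cls in aset.te_classes}
    records: list[OverlapRecord] = []
    for gene in genes:
        for t in gene.transcripts:
            for exon in t.exons:
                for cls in aset.te_classes:
                    covered = intersect_length([exon], merged[cls])
                    if covered < min_frac * exon.length:
                        continue
                    sf, tied = _attribute_superfamily(exon, trees[cls])
                    records.append(
                        OverlapRecord(
                            gene_id=gene.gene_id,
                            transcript_id=t.transcript_id,
                            exon=exon,
                            te_class=cls,
                            superfamily=sf,
                            covered_fraction=covered / exon.length,
                            tied_superfamilies=tied,
                        )
                    )
    return records


def superfamily_tally(
    records: list[OverlapRecord], min_count: int = 20
) -> pd.DataFrame:
    """Transcripts supporting each (class, superfamily), filtered to counts
    >= ``min_count``.

    A transcript covered several times by the same superfamily counts once;
    records without a superfamily (Simple_repeat / Low_complexity / Unknown
    classes) are not tallied.  Sorted by count descending, then class and
    superfamily names.
    """
    seen = {
        (r.transcript_id, r.te_class, r.superfamily)
        for r in records
        if r.superfamily
    }
    counts = Counter((cls, sf) for _, cls, sf in seen)
    rows = [
        {"te_class": cls.value, "superfamily": sf, "n_transcripts": n}
        for (cls, sf), n in counts.items()
        if n >= min_count
    ]
    df = pd.DataFrame(rows, columns=["te_class", "superfamily", "n_transcripts"])
    return df.sort_values(
        ["n_transcripts", "te_class", "superfamily"],
        ascending=[False, True, True],
        ignore_index=True,
    )


def gene_class_map(records: list[OverlapRecord]) -> dict[str, set[TEClass]]:
    """gene_id -> set of repeat classes it overlaps (input to phylostrata)."""
    out: dict[str, set[TEClass]] = {}
    for r in records:
        out.setdefault(r.gene_id, set()).add(r.te_class)
    return out


def records_to_frame(records: list[OverlapRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "transcript_id": r.transcript_id,
            "chrom": r.exon.chrom,
            "start": r.exon.start,
            "end": r.exon.end,
            "te_class": r.te_class.value,
            "superfamily": r.superfamily,
            "covered_fraction": r.covered_fraction,
            "tied_superfamilies": ",".join(r.tied_superfamilies),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "transcript_id",
            "chrom",
            "start",
            "end",
            "te_class",
            "superfamily",
            "covered_fraction",
            "tied_superfamilies",
        ],
    )
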