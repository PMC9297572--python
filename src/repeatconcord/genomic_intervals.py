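"""Coordinate conventions, interval algebra, windowing and flat-file IO.

Everything downstream (mask concordance, TE density profiles, repeat-gene
overlap) is built on the primitives in this module.  Conventions:

* Coordinates are 0-based, half-open ``[start, end)`` — the BED convention —
  so ``end - start`` is always the length in bases.  GFF3 input (1-based,
  inclusive) is converted at the boundary.
* Interval arithmetic is strand-agnostic: a repeat mask is a set of genomic
  bases, not a set of stranded features.
* Touching intervals (``a.end == b.start``) merge; a base-level mask has no
  meaningful zero-width gap.
* Records extending beyond the bound chromosome length are rejected rather
  than clipped, so a fixture/index mismatch surfaces immediately.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TEClass",
    "GenomeIndex",
    "Interval",
    "RepeatElement",
    "RepeatAnnotationSet",
    "WindowGrid",
    "make_windows",
    "merge_intervals",
    "intersect_length",
    "intersect",
    "coverage_fraction",
    "total_masked_bases",
    "window_coverage_bases",
    "read_genome_index",
    "write_genome_index",
    "read_bed",
    "write_bed",
    "read_gff3_genes",
    "write_gff3_genes",
    "parse_repeat_name",
    "format_repeat_name",
    "BedParseError",
    "ValidationError",
]


class BedParseError(ValueError):
    """A malformed line in a BED-like file; the message carries the line number."""


class ValidationError(ValueError):
    """A record inconsistent with the bound genome index or a type invariant."""


class TEClass(str, Enum):
    """Repeat classes following the Wicker hierarchy as flattened by RepeatMasker-style
    naming: class I retrotransposons (LINE, LTR, SINE, Penelope), class II DNA
    transposons (DNA, rolling-circle Helitrons), plus non-TE repeat categories."""

    DNA = "DNA"
    LINE = "LINE"
    LTR = "LTR"
    RC_HELITRON = "RC"
    PENELOPE = "Penelope"
    SINE = "SINE"
    SIMPLE_REPEAT = "Simple_repeat"
    LOW_COMPLEXITY = "Low_complexity"
    UNKNOWN = "Unknown"


#: classes that never carry a superfamily label
UNCLASSIFIED_CLASSES = frozenset(
    {TEClass.UNKNOWN, TEClass.SIMPLE_REPEAT, TEClass.LOW_COMPLEXITY}
)


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths; the frame every interval is validated
    against."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in genome index")
        for chrom, length in self.entries:
            if length < 1:
                raise ValidationError(f"chromosome {chrom} has length {length} < 1")

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.entries)

    def validate_interval(self, iv: Interval, *, context: str = "") -> None:
        lengths = self.lengths
        if iv.chrom not in lengths:
            raise ValidationError(
                f"{context or 'interval'} {iv.chrom}:{iv.start}-{iv.end}: "
                f"unknown chromosome {iv.chrom!r}"
            )
        if iv.end > lengths[iv.chrom]:
            raise ValidationError(
                f"{context or 'interval'} {iv.chrom}:{iv.start}-{iv.end} extends past "
                f"chromosome end ({lengths[iv.chrom]})"
            )


@dataclass(frozen=True)
class RepeatElement:
    """One annotated repeat: an interval plus its class/superfamily and the tool
    ('source') that called it."""

    interval: Interval
    te_class: TEClass = TEClass.UNKNOWN
    superfamily: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.superfamily and self.te_class in UNCLASSIFIED_CLASSES:
            raise ValidationError(
                f"superfamily {self.superfamily!r} not allowed for class "
                f"{self.te_class.value}"
            )


@dataclass
class RepeatAnnotationSet:
    """All elements called by one source tool, optionally bound to a genome index."""

    source: str
    elements: list[RepeatElement] = field(default_factory=list)
    index: GenomeIndex | None = None

    def __post_init__(self) -> None:
        if self.index is not None:
            for el in self.elements:
                self.index.validate_interval(
                    el.interval, context=f"element from {self.source}"
                )

    def intervals(self, te_class: TEClass | None = None) -> list[Interval]:
        """Raw (unmerged) intervals, optionally restricted to one class."""
        if te_class is None:
            return [el.interval for el in self.elements]
        return [el.interval for el in self.elements if el.te_class == te_class]

    def merged(self, te_class: TEClass | None = None) -> list[Interval]:
        return merge_intervals(self.intervals(te_class))

    @property
    def te_classes(self) -> list[TEClass]:
        seen: dict[TEClass, None] = {}
        for el in self.elements:
            seen.setdefault(el.te_class)
        return list(seen)


@dataclass(frozen=True)
class WindowGrid:
    """Consecutive fixed-width windows tiling each chromosome from 0; the trailing
    window of a chromosome may be shorter."""

    window_size: int
    windows: tuple[Interval, ...]
    index: GenomeIndex

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def chrom_offsets(self) -> dict[str, tuple[int, int]]:
        """Map chrom -> (first window index, number of windows)."""
        out: dict[str, tuple[int, int]] = {}
        for chrom, group in itertools.groupby(
            enumerate(self.windows), key=lambda t: t[1].chrom
        ):
            items = list(group)
            out[chrom] = (items[0][0], len(items))
        return out

    def window_lengths(self) -> np.ndarray:
        return np.array([w.length for w in self.windows], dtype=np.int64)


def make_windows(index: GenomeIndex, window_size: int) -> WindowGrid:
    """Tile every chromosome with consecutive ``window_size``-bp windows.

    The trailing partial window of each chromosome is retained, so the window
    lengths always sum to the genome length.
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    windows: list[Interval] = []
    for chrom, length in index.entries:
        for start in range(0, length, window_size):
            windows.append(Interval(chrom, start, min(start + window_size, length)))
    return WindowGrid(window_size=window_size, windows=tuple(windows), index=index)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Minimal sorted set of disjoint intervals covering the same bases.

    Touching intervals (``end == start``) are merged.  Output is sorted by
    (chrom, start); chromosomes sort lexicographically.
    """
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Disjoint intervals covering the bases present in both inputs (each merged
    first); linear sweep over the two sorted lists."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(ma) and j < len(mb):
        x, y = ma[i], mb[j]
        if x.chrom == y.chrom:
            lo, hi = max(x.start, y.start), min(x.end, y.end)
            if lo < hi:
                out.append(Interval(x.chrom, lo, hi))
            # advance whichever ends first
            if x.end <= y.end:
                i += 1
            else:
                j += 1
        elif x.chrom < y.chrom:
            i += 1
        else:
            j += 1
    return out


def intersect_length(a: Iterable[Interval], b: Iterable[Interval]) -> int:
    """Total bases shared by the two interval sets; commutative."""
    return sum(iv.length for iv in intersect(a, b))


def coverage_fraction(target: Interval, mask: Iterable[Interval]) -> float:
    """Fraction of ``target`` bases covered by the merged ``mask``; in [0, 1]."""
    covered = intersect_length([target], mask)
    return covered / target.length


def total_masked_bases(aset: RepeatAnnotationSet) -> int:
    """Bases covered by the union of all elements; nested/duplicate copies count
    once."""
    return sum(iv.length for iv in aset.merged())


def window_coverage_bases(mask: Iterable[Interval], grid: WindowGrid) -> np.ndarray:
    """Covered bases per grid window for a (merged) mask; int64 vector of
    length ``grid.n_windows``.

    Exact: summing ``out`` recovers the merged mask length for intervals on
    chromosomes present in the grid.
    """
    w = grid.window_size
    offsets = grid.chrom_offsets()
    out = np.zeros(grid.n_windows, dtype=np.int64)
    for iv in merge_intervals(mask):
        if iv.chrom not in offsets:
            raise ValidationError(
                f"interval on {iv.chrom!r} not covered by the window grid"
            )
        off, nwin = offsets[iv.chrom]
        w0, w1 = iv.start // w, (iv.end - 1) // w
        if w1 >= nwin:
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} extends past the grid"
            )
        if w0 == w1:
            out[off + w0] += iv.length
        else:
            out[off + w0] += (w0 + 1) * w - iv.start
            out[off + w1] += iv.end - w1 * w
            out[off + w0 + 1 : off + w1] += w
    return out


# ---------------------------------------------------------------------------
# flat-file IO
# ---------------------------------------------------------------------------


def read_genome_index(path: str | Path) -> GenomeIndex:
    """Read a two-column ``chrom<TAB>length`` TSV (e.g. a .fai prefix)."""
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(
                    f"{path}:{lineno}: expected 'chrom<TAB>length', got {line!r}"
                )
            try:
                entries.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from exc
    return GenomeIndex(entries=tuple(entries))


def write_genome_index(index: GenomeIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in index.entries:
            fh.write(f"{chrom}\t{length}\n")


def parse_repeat_name(name: str) -> tuple[TEClass, str]:
    """Parse a RepeatMasker-style name field 'class/superfamily' (e.g. 'LINE/CR1',
    'RC/Helitron', bare 'Simple_repeat')."""
    cls_str, _, superfamily = name.partition("/")
    try:
        te_class = TEClass(cls_str)
    except ValueError:
        te_class = TEClass.UNKNOWN
        superfamily = ""
    if te_class in UNCLASSIFIED_CLASSES:
        superfamily = ""
    return te_class, superfamily


def format_repeat_name(te_class: TEClass, superfamily: str) -> str:
    if superfamily:
        return f"{te_class.value}/{superfamily}"
    return te_class.value


def read_bed(
    path: str | Path,
    source: str | None = None,
    index: GenomeIndex | None = None,
) -> RepeatAnnotationSet:
    """Read a BED6-like repeat annotation file.

    Columns: chrom, start, end, name ('class/superfamily'), score ('.' allowed),
    strand ('.' allowed); name/score/strand optional.  '#' header lines skipped.
    Malformed lines raise :class:`BedParseError` with the line number; intervals
    beyond the index raise :class:`ValidationError` naming the record.
    """
    if source is None:
        source = Path(path).stem
    elements: list[RepeatElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got "
                    f"{len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1:3]!r}"
                ) from exc
            try:
                iv = Interval(fields[0], start, end)
            except ValidationError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            te_class, superfamily = (
                parse_repeat_name(fields[3])
                if len(fields) > 3
                else (TEClass.UNKNOWN, "")
            )
            elements.append(
                RepeatElement(
                    interval=iv,
                    te_class=te_class,
                    superfamily=superfamily,
                    source=source,
                )
            )
    return RepeatAnnotationSet(source=source, elements=elements, index=index)


def write_bed(aset: RepeatAnnotationSet, path: str | Path) -> None:
    """Write BED6 with the 'class/superfamily' name convention; score/strand as '.'."""
    with open(path, "w") as fh:
        for el in aset.elements:
            iv = el.interval
            name = format_repeat_name(el.te_class, el.superfamily)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t.\t.\n")


def read_gff3_genes(path: str | Path, index: GenomeIndex | None = None):
    """Read gene/mRNA/exon features from GFF3 into :class:`~repeatconcord.gene_overlap.GeneModel`
    objects (1-based inclusive converted to 0-based half-open)."""
    import gffutils

    from .gene_overlap import GeneModel, Transcript

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts: list[Transcript] = []
        for t in db.children(gene, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = sorted(
                Interval(e.seqid, e.start - 1, e.end)
                for e in db.children(t, featuretype="exon")
            )
            if index is not None:
                for exon in exons:
                    index.validate_interval(exon, context=f"exon of {t.id}")
            transcripts.append(
                Transcript(transcript_id=t.id, exons=tuple(exons), strand=t.strand or ".")
            )
        if transcripts:
            genes.append(GeneModel(gene_id=gene.id, transcripts=tuple(transcripts)))
    return genes


def write_gff3_genes(genes: Sequence, path: str | Path) -> None:
    """Write gene models as minimal GFF3 (gene/mRNA/exon rows, back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            g_chrom = gene.transcripts[0].exons[0].chrom
            g_start = min(e.start for t in gene.transcripts for e in t.exons)
            g_end = max(e.end for t in gene.transcripts for e in t.exons)
            strand = gene.transcripts[0].strand
            fh.write(
                f"{g_chrom}\t.\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
                f"ID={gene.gene_id}\n"
            )
            for t in gene.transcripts:
                t_start = min(e.start for e in t.exons)
                t_end = max(e.end for e in t.exons)
                fh.write(
                    f"{g_chrom}\t.\tmRNA\t{t_start + 1}\t{t_end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={gene.gene_id}\n"
                )
                for k, e in enumerate(t.exons, 1):
                    fh.write(
                        f"{e.chrom}\t.\texon\t{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t"
                        f"ID={t.transcript_id}.exon{k};Parent={t.transcript_id}\n"
                    )
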