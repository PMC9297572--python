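"""Per-class TE composition summaries and chromosomal density profiles.

Composition is reported both as merged masked base pairs (how much of the
genome each class occupies) and as raw element counts (how many annotated
regions), since the two views rank classes differently when element length
distributions differ.  Density profiles give the fraction of each fixed-width
window (5 kb in the supported study design) covered by one class, which is the
standard input for circular/linear chromosome plots showing arm enrichment.
"""

from __future__ import annotations

import pandas as pd

from .genomic_intervals import (
    Interval,
    RepeatAnnotationSet,
    TEClass,
    WindowGrid,
    merge_intervals,
    window_coverage_bases,
)

__all__ = ["composition_summary", "density_profile", "class_mask"]


def class_mask(
    aset: RepeatAnnotationSet,
    te_class: TEClass,
    merge_penelope: bool = False,
) -> list[Interval]:
    """Merged intervals of one class; with ``merge_penelope`` Penelope elements
    are folded into LINE (some annotators cannot separate the two)."""
    ivs = aset.intervals(te_class)
    if merge_penelope and te_class == TEClass.LINE:
        ivs = ivs + aset.intervals(TEClass.PENELOPE)
    return merge_intervals(ivs)


def composition_summary(
    aset: RepeatAnnotationSet, merge_penelope: bool = False
) -> pd.DataFrame:
    """Per-class merged bp and raw element counts, bp-descending.

    Base pairs are merged within each class (overlapping same-class elements
    count once); element counts are raw.  Empty input yields an empty table.
    """
    classes = aset.te_classes
    if merge_penelope:
        classes = [c for c in classes if c != TEClass.PENELOPE]
    rows = []
    for cls in classes:
        mask = class_mask(aset, cls, merge_penelope=merge_penelope)
        n = sum(1 for el in aset.elements if el.te_class == cls)
        if merge_penelope and cls == TEClass.LINE:
            n += sum(1 for el in aset.elements if el.te_class == TEClass.PENELOPE)
        rows.append(
            {
                "te_class": cls.value,
                "masked_bp": sum(iv.length for iv in mask),
                "n_elements": n,
            }
        )
    df = pd.DataFrame(rows, columns=["te_class", "masked_bp", "n_elements"])
    return df.sort_values(
        ["masked_bp", "te_class"], ascending=[False, True], ignore_index=True
    )


def density_profile(
    aset: RepeatAnnotationSet,
    grid: WindowGrid,
    te_class: TEClass | str,
    merge_penelope: bool = False,
) -> pd.DataFrame:
    """Fraction of each window covered by one TE class (merged elements).

    Returns a (chrom, start, end, fraction) table aligned with ``grid``.
    Conservation holds exactly: ``sum(fraction * window length)`` equals the
    class's merged masked bp.
    """
    if not isinstance(te_class, TEClass):
        try:
            te_class = TEClass(te_class)
        except ValueError:
            raise ValueError(f"unknown TE class {te_class!r}") from None
    mask = class_mask(aset, te_class, merge_penelope=merge_penelope)
    bases = window_coverage_bases(mask, grid)
    lengths = grid.window_lengths()
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in grid.windows],
            "start": [w.start for w in grid.windows],
            "end": [w.end for w in grid.windows],
            "fraction": bases / lengths,
        }
    )
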