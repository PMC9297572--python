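"""Phylostratigraphic age classes and per-class repeat contributions.

Genes are dated by the most distant species of an ordered ladder (nearest
relative = index 1, most distant = K) in which a homology hit is found; a gene
with no hit anywhere is focal-species-specific (age class 0).  Hit tables are
consumed as input — the homology search itself is out of scope — either as 0/1
indicators or as e-values with a strict ``< threshold`` rule.

Given an overlap map from the repeat-gene screen (gene -> repeat classes
covering at least half of one exon), per-age-class contributions report what
fraction of each stratum overlaps each repeat class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genomic_intervals import TEClass, ValidationError

__all__ = [
    "HitTable",
    "assign_age_classes",
    "repeat_contribution_by_age",
    "read_hit_table",
]


@dataclass
class HitTable:
    """gene x species homology matrix over an ordered species ladder.

    ``hits`` is indexed by gene id with one column per species in
    ``species_order`` (nearest first).  Boolean/0-1 values are hit indicators;
    any other numeric values are e-values ("no hit" must be encoded as a value
    at or above the threshold, e.g. 1).  NaN entries are rejected.
    """

    species_order: tuple[str, ...]
    hits: pd.DataFrame

    def __post_init__(self) -> None:
        if len(set(self.species_order)) != len(self.species_order):
            raise ValidationError("duplicate species in species_order")
        missing = [s for s in self.species_order if s not in self.hits.columns]
        if missing:
            raise ValidationError(f"hit table lacks species columns {missing}")
        self.hits = self.hits[list(self.species_order)]
        if self.hits.isna().any().any():
            bad = self.hits.index[self.hits.isna().any(axis=1)][:5].tolist()
            raise ValidationError(
                f"hit table has missing entries, e.g. for genes {bad}"
            )

    @property
    def n_species(self) -> int:
        return len(self.species_order)

    @property
    def is_boolean(self) -> bool:
        vals = self.hits.to_numpy()
        if vals.dtype == bool:
            return True
        return bool(np.isin(vals, (0, 1)).all())


def assign_age_classes(ht: HitTable, evalue_threshold: float = 1e-5) -> pd.Series:
    """Age class per gene: the largest species index (1..K) with a qualifying
    hit, 0 when there is none.

    For e-value tables a hit is ``value < evalue_threshold`` (strict).
    Non-monotone hit patterns are allowed; only the maximum index matters.
    """
    if ht.is_boolean:
        mask = ht.hits.to_numpy().astype(bool)
    else:
        mask = ht.hits.to_numpy() < evalue_threshold
    idx = np.arange(1, ht.n_species + 1)
    classes = np.where(mask.any(axis=1), (mask * idx).max(axis=1), 0)
    return pd.Series(classes, index=ht.hits.index, name="age_class")


def repeat_contribution_by_age(
    assign: pd.Series,
    overlap_genes: Mapping[str, set],
    n_classes: int | None = None,
) -> pd.DataFrame:
    """Per (age class, repeat class): stratum size, overlapping genes, fraction.

    ``overlap_genes`` maps gene id -> set of TEClass (genes absent from the map
    overlap nothing); every key must be an assigned gene.  Empty age classes
    report NaN fractions rather than 0.  All classes 0..``n_classes`` (default:
    max assigned class) appear in the output for every repeat class seen.
    """
    unknown = [g for g in overlap_genes if g not in assign.index]
    if unknown:
        raise ValidationError(
            f"overlap map names genes absent from the assignment, e.g. {unknown[:5]}"
        )
    if n_classes is None:
        n_classes = int(assign.max()) if len(assign) else 0
    class_sizes = assign.value_counts().to_dict()
    te_classes = sorted(
        {cls for classes in overlap_genes.values() for cls in classes},
        key=lambda c: c.value,
    )
    counts: dict[tuple[int, TEClass], int] = {}
    for gene, classes in overlap_genes.items():
        age = int(assign[gene])
        for cls in classes:
            counts[(age, cls)] = counts.get((age, cls), 0) + 1
    rows = []
    for age in range(n_classes + 1):
        size = int(class_sizes.get(age, 0))
        for cls in te_classes:
            n = counts.get((age, cls), 0)
            rows.append(
                {
                    "age_class": age,
                    "te_class": cls.value,
                    "n_genes": size,
                    "n_overlapping": n,
                    "fraction": (n / size) if size else float("nan"),
                }
            )
    return pd.DataFrame(
        rows, columns=["age_class", "te_class", "n_genes", "n_overlapping", "fraction"]
    )


def read_hit_table(path: str | Path, species_order: list[str] | None = None) -> HitTable:
    """Read a gene_id + one-column-per-species TSV; the header gives the species
    ladder (nearest -> most distant) unless ``species_order`` overrides it."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    order = tuple(species_order) if species_order else tuple(df.columns)
    return HitTable(species_order=order, hits=df)
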