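"""Agreement analysis for competing TE classifiers.

Three classifiers label the same elements at order level (DNA, LINE, LTR,
SINE, RC, Penelope, ...); orders map deterministically onto two broad classes
— DNA transposon (DNA, rolling-circle) versus retrotransposon (LINE, LTR,
SINE, Penelope) — with everything else treated as Other/Unknown.  The module
provides order-level cross-classification matrices between method pairs, a
class-level majority vote with an AMBIGUOUS outcome when all three disagree,
and a consensus report (unanimity rate, per-method error rates against either
an external truth channel or the majority consensus).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "CLASS_DNA",
    "CLASS_RETRO",
    "CLASS_OTHER",
    "AMBIGUOUS",
    "order_to_class",
    "LabelTable",
    "VoteResult",
    "ConsensusReport",
    "cross_classification_matrix",
    "majority_vote",
    "consensus_report",
    "read_label_table",
]

CLASS_DNA = "DNA_transposon"
CLASS_RETRO = "Retrotransposon"
CLASS_OTHER = "Other"
AMBIGUOUS = "AMBIGUOUS"

_ORDER_TO_CLASS = {
    "DNA": CLASS_DNA,
    "RC": CLASS_DNA,
    "RC_Helitron": CLASS_DNA,
    "Helitron": CLASS_DNA,
    "LINE": CLASS_RETRO,
    "LTR": CLASS_RETRO,
    "SINE": CLASS_RETRO,
    "Penelope": CLASS_RETRO,
}


def order_to_class(order_label: str) -> str:
    """Map an order-level label to {DNA_transposon, Retrotransposon, Other}."""
    return _ORDER_TO_CLASS.get(order_label, CLASS_OTHER)


@dataclass
class LabelTable:
    """element x method order-level labels; class-level labels are derived."""

    orders: pd.DataFrame  # index: element_id, columns: methods

    def __post_init__(self) -> None:
        if self.orders.isna().any().any():
            bad = self.orders.index[self.orders.isna().any(axis=1)][:5].tolist()
            raise ValueError(f"missing labels for elements {bad}")

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(self.orders.columns)

    @property
    def classes(self) -> pd.DataFrame:
        return self.orders.map(order_to_class)

    @property
    def n_elements(self) -> int:
        return len(self.orders)


@dataclass(frozen=True)
class VoteResult:
    label: str  # consensus class label or AMBIGUOUS
    unanimous: bool


@dataclass
class ConsensusReport:
    unanimity_rate: float
    error_rates: dict[str, float]
    n_elements: int
    n_reference: dict[str, int]  # per-method error-rate denominator


def cross_classification_matrix(
    lt: LabelTable, method_a: str, method_b: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Order-level contingency matrix (counts, row-normalized fractions).

    Rows are ``method_a`` labels, columns ``method_b``; fractions of nonempty
    rows sum to 1.  The grand total of counts equals the element count.
    """
    for m in (method_a, method_b):
        if m not in lt.methods:
            raise KeyError(f"unknown method {m!r}; have {list(lt.methods)}")
    counts = pd.crosstab(lt.orders[method_a], lt.orders[method_b])
    counts.index.name, counts.columns.name = method_a, method_b
    fractions = counts.div(counts.sum(axis=1), axis=0)
    return counts, fractions


def _require_three(lt: LabelTable) -> None:
    if len(lt.methods) != 3:
        raise ValueError(
            f"majority vote is defined for exactly 3 methods, got {len(lt.methods)}"
        )


def majority_vote(lt: LabelTable, element_id, level: str = "class") -> VoteResult:
    """Consensus label held by >= 2 of the 3 methods, or AMBIGUOUS.

    Default granularity is the two-class level (at class level a three-way
    split needs an Other/Unknown vote); ``level='order'`` votes on raw order
    labels instead.  Symmetric under permutation of methods.
    """
    _require_three(lt)
    table = lt.classes if level == "class" else lt.orders
    if element_id not in table.index:
        raise KeyError(f"unknown element {element_id!r}")
    votes = list(table.loc[element_id])
    for label in set(votes):
        if votes.count(label) >= 2:
            return VoteResult(label=label, unanimous=votes.count(label) == 3)
    return VoteResult(label=AMBIGUOUS, unanimous=False)


def consensus_report(
    lt: LabelTable,
    truth: Mapping[str, str] | pd.Series | None = None,
    level: str = "class",
) -> ConsensusReport:
    """Unanimity rate and per-method error rates.

    Unanimity is the fraction of elements where all three methods give the
    same label.  Errors are counted against the external truth when provided
    (over all elements); otherwise against the majority consensus, with
    AMBIGUOUS elements excluded from the denominator.
    """
    _require_three(lt)
    if lt.n_elements == 0:
        raise ValueError("empty label table")
    table = lt.classes if level == "class" else lt.orders
    nunique = table.nunique(axis=1)
    unanimity = float((nunique == 1).mean())
    if truth is not None:
        ref = pd.Series(dict(truth) if not isinstance(truth, pd.Series) else truth)
        missing = table.index.difference(ref.index)
        if len(missing):
            raise ValueError(f"truth lacks elements, e.g. {missing[:5].tolist()}")
        ref = ref.reindex(table.index)
    else:
        votes = table.apply(
            lambda row: next(
                (lab for lab in set(row) if list(row).count(lab) >= 2), AMBIGUOUS
            ),
            axis=1,
        )
        ref = votes.where(votes != AMBIGUOUS)
    valid = ref.notna()
    error_rates, n_ref = {}, {}
    for m in lt.methods:
        n = int(valid.sum())
        n_ref[m] = n
        error_rates[m] = (
            float((table.loc[valid, m] != ref[valid]).mean()) if n else float("nan")
        )
    return ConsensusReport(
        unanimity_rate=unanimity,
        error_rates=error_rates,
        n_elements=lt.n_elements,
        n_reference=n_ref,
    )


def read_label_table(path: str | Path) -> LabelTable:
    """Read a long-format TSV (element_id, method, order_label) and pivot to
    the element x method table; every element needs a label from every method."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"element_id", "method", "order_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"label TSV needs columns {sorted(required)}")
    wide = df.pivot(index="element_id", columns="method", values="order_label")
    return LabelTable(orders=wide)
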