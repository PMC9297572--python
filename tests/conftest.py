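import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from repeatconcord.genomic_intervals import (
    GenomeIndex,
    Interval,
    RepeatAnnotationSet,
    RepeatElement,
    TEClass,
)


@pytest.fixture
def small_index() -> GenomeIndex:
    return GenomeIndex(entries=(("chr1", 10_000), ("chr2", 5_000)))


def random_intervals(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    n_max: int = 50,
    max_len: int = 800,
) -> list[Interval]:
    """Up to n_max random intervals across the given chromosomes."""
    out = []
    chroms = list(chrom_lengths)
    for _ in range(int(rng.integers(1, n_max + 1))):
        chrom = chroms[rng.integers(0, len(chroms))]
        clen = chrom_lengths[chrom]
        length = int(rng.integers(1, min(max_len, clen) + 1))
        start = int(rng.integers(0, clen - length + 1))
        out.append(Interval(chrom, start, start + length))
    return out


def make_set(
    intervals, source="toolX", te_class=TEClass.UNKNOWN, index=None
) -> RepeatAnnotationSet:
    return RepeatAnnotationSet(
        source=source,
        elements=[
            RepeatElement(interval=iv, te_class=te_class, source=source)
            for iv in intervals
        ],
        index=index,
    )
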