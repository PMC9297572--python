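"""Seeded generators for every fixture type the analysis modules consume.

The generators replace the nematode assembly and the external repeat finders,
classifiers and orthology tools with deterministic stand-ins: each returns
both in-memory domain objects (plus writers for the flat-file dialects) and a
ground-truth registry, so downstream results can be checked against what was
planted rather than re-derived from the fixtures.

Defaults describe a desk-scale study: a 1-Mb genome in three chromosomes with
~20% of bases in planted repeats (real nematode genomes bracket this between
roughly 12% and 24%), six emulated annotation tools including two internally
correlated pairs, a nine-species homology ladder, three classifiers with
distinct error rates, and three-species gene orders with planted focal-lineage
insertions.

Reproducibility contract: one global seed feeds independent named substreams
(one per generator, keyed by stable CRC32 hashes), so identical configs give
byte-identical fixture files and adding a generator never perturbs existing
ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier_consensus import CLASS_DNA, CLASS_RETRO, LabelTable
from .gene_overlap import GeneModel, Transcript
from .genomic_intervals import (
    GenomeIndex,
    Interval,
    RepeatAnnotationSet,
    RepeatElement,
    TEClass,
    intersect_length,
    merge_intervals,
)
from .phylostrata import HitTable
from .synteny import UNASSIGNED, GeneOrder

__all__ = [
    "SimConfig",
    "ClassProfile",
    "ToolProfile",
    "GeneFixtureConfig",
    "HitTableConfig",
    "LabelConfig",
    "GeneOrderConfig",
    "AnnotationSuite",
    "GeneFixture",
    "HitTableFixture",
    "LabelFixture",
    "GeneOrderFixture",
    "simulate_annotation_suite",
    "simulate_gene_fixture",
    "simulate_hit_table",
    "simulate_labels",
    "simulate_gene_orders",
]


def _rng(seed: int, *keys: str) -> np.random.Generator:
    """Independent substream for (seed, keys): stable across generator additions."""
    spawn_key = tuple(zlib.crc32(k.encode()) for k in keys)
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=spawn_key))
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ClassProfile:
    """Planted repeat landscape for one class: genome fraction, element length
    scale (gamma with shape 2), superfamily mix, and arm bias (0 = uniform;
    b > 0 weights positions by 1 + b*2*|x - 0.5| along the chromosome)."""

    density: float
    mean_length: int
    superfamilies: dict[str, float] = field(default_factory=dict)
    arm_bias: float = 0.0
    min_length: int = 30


@dataclass
class ToolProfile:
    """Emulated annotation tool.

    Tools sharing a ``latent_partner`` id derive from one latent subsample of
    the true mask (drawn at ``sensitivity``), then each drops latent elements
    at ``flip_noise``; unpartnered tools subsample the true mask directly at
    ``sensitivity``.  Endpoints are jittered (normal, sd ``jitter_sd``) and
    false calls are added to ``fp_density`` of the genome.
    """

    name: str
    sensitivity: float = 0.9
    fp_density: float = 0.01
    jitter_sd: float = 5.0
    latent_partner: str | None = None
    flip_noise: float = 0.05


def _default_class_profiles() -> dict[TEClass, ClassProfile]:
    return {
        TEClass.LINE: ClassProfile(
            0.06, 800, {"CR1": 0.45, "RTE": 0.35, "Vingi": 0.20}, arm_bias=2.0
        ),
        TEClass.DNA: ClassProfile(
            0.05,
            600,
            {"Sola-3": 0.30, "TcMar-Tc1": 0.30, "TcMar-m44": 0.20, "Zisupton": 0.20},
        ),
        TEClass.SIMPLE_REPEAT: ClassProfile(0.04, 120),
        TEClass.LTR: ClassProfile(0.02, 1500, {"Gypsy": 0.5, "Pao": 0.5}, arm_bias=2.0),
        TEClass.RC_HELITRON: ClassProfile(0.01, 800, {"Helitron": 1.0}),
        TEClass.PENELOPE: ClassProfile(0.01, 900, {"Penelope": 1.0}, arm_bias=2.0),
        TEClass.LOW_COMPLEXITY: ClassProfile(0.01, 80),
    }


def _default_tools() -> list[ToolProfile]:
    return [
        ToolProfile("rm2", sensitivity=0.92, fp_density=0.005, jitter_sd=5.0, latent_partner="pairA"),
        ToolProfile("red", sensitivity=0.92, fp_density=0.010, jitter_sd=8.0, latent_partner="pairA"),
        ToolProfile("dustmasker", sensitivity=0.85, fp_density=0.010, jitter_sd=4.0, latent_partner="pairB"),
        ToolProfile("sdust", sensitivity=0.85, fp_density=0.012, jitter_sd=4.0, latent_partner="pairB"),
        ToolProfile("tallymer", sensitivity=0.70, fp_density=0.020, jitter_sd=15.0),
        ToolProfile("trf", sensitivity=0.40, fp_density=0.005, jitter_sd=10.0),
    ]


@dataclass
class GeneFixtureConfig:
    """Planted gene-model outcomes, keyed by (class value, superfamily) for the
    containment channel.  Default counts put six superfamilies at or above the
    20-transcript cutoff and two below it."""

    contained_per_superfamily: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("LINE", "CR1"): 30,
            ("LINE", "RTE"): 24,
            ("DNA", "Sola-3"): 25,
            ("DNA", "TcMar-Tc1"): 22,
            ("LTR", "Gypsy"): 21,
            ("LTR", "Pao"): 20,
            ("LINE", "Vingi"): 5,
            ("DNA", "TcMar-m44"): 4,
        }
    )
    n_half_covered: int = 15
    n_below_half: int = 10
    n_shortfall: int = 10
    #: sized so contained transcripts are ~14% of the single-exon channel
    n_clear_se: int = 920
    n_clear_multi: int = 10
    n_multi_isoform: int = 10


@dataclass
class HitTableConfig:
    n_genes: int = 5000
    species: tuple[str, ...] = (
        "P_exspectatus",
        "P_arcanus",
        "P_maxplancki",
        "P_japonicus",
        "P_mayeri",
        "P_entomophagus",
        "P_fissidentatus",
        "Parapristionchus_giblindavisi",
        "Micoletzkya_japonica",
    )
    #: age-class proportions 0..K; class 0 near one third (orphan-rich genomes)
    proportions: tuple[float, ...] = (
        0.30, 0.07, 0.06, 0.05, 0.05, 0.04, 0.05, 0.07, 0.11, 0.20,
    )
    near_hit_prob: float = 0.9
    sporadic_rate: float = 0.0
    #: planted per-age-class overlap fractions; the simple-repeat series rises
    #: with age and dips at class 5
    overlap_fractions: dict[TEClass, tuple[float, ...]] = field(
        default_factory=lambda: {
            TEClass.SIMPLE_REPEAT: (
                0.060, 0.074, 0.088, 0.102, 0.116, 0.060, 0.144, 0.158, 0.173, 0.186,
            ),
            TEClass.DNA: (0.05,) * 10,
            TEClass.LINE: (0.05,) * 10,
            TEClass.LTR: (0.03,) * 10,
        }
    )


@dataclass
class LabelConfig:
    n_elements: int = 200
    methods: tuple[str, ...] = ("rm2", "deepte", "rfsb")
    flip_rates: tuple[float, ...] = (0.05, 0.15, 0.25)
    retro_fraction: float = 0.5
    unknown_rate: float = 0.0


@dataclass
class GeneOrderConfig:
    species: tuple[str, ...] = ("P_pacificus", "P_exspectatus", "P_arcanus")
    n_scaffolds: int = 2
    families_per_scaffold: int = 250
    n_insertions: int = 20
    shuffle_rate: float = 0.05
    dup_rate: float = 0.02
    unassigned_rate: float = 0.02
    target_family: str = "Zisupton"
    reverse_out2: bool = True


@dataclass
class SimConfig:
    """Study configuration; ``seed`` is mandatory, everything else defaulted."""

    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrI": 400_000, "chrII": 300_000, "chrIII": 300_000}
    )
    class_profiles: dict[TEClass, ClassProfile] = field(
        default_factory=_default_class_profiles
    )
    tools: list[ToolProfile] = field(default_factory=_default_tools)
    genes: GeneFixtureConfig = field(default_factory=GeneFixtureConfig)
    hits: HitTableConfig = field(default_factory=HitTableConfig)
    labels: LabelConfig = field(default_factory=LabelConfig)
    orders: GeneOrderConfig = field(default_factory=GeneOrderConfig)

    def __post_init__(self) -> None:
        for cls, prof in self.class_profiles.items():
            if not 0 <= prof.density <= 1:
                raise ValueError(f"density for {cls.value} outside [0, 1]")
        for tool in self.tools:
            for p in (tool.sensitivity, tool.fp_density, tool.flip_noise):
                if not 0 <= p <= 1:
                    raise ValueError(f"tool {tool.name}: probability {p} outside [0, 1]")

    @property
    def index(self) -> GenomeIndex:
        return GenomeIndex(entries=tuple(self.chrom_lengths.items()))


# ---------------------------------------------------------------------------
# annotation suite
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSuite:
    index: GenomeIndex
    true_set: RepeatAnnotationSet
    tool_sets: list[RepeatAnnotationSet]
    registry: dict


class _Placer:
    """Sorted occupancy list per (chrom, key) for overlap-free placement."""

    def __init__(self) -> None:
        self._occ: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def try_place(self, chrom: str, key: str, start: int, end: int) -> bool:
        import bisect

        occ = self._occ.setdefault((chrom, key), [])
        i = bisect.bisect_left(occ, (start, end))
        if i > 0 and occ[i - 1][1] > start:
            return False
        if i < len(occ) and occ[i][0] < end:
            return False
        occ.insert(i, (start, end))
        return True


def _sample_position(rng: np.random.Generator, chrom_len: int, length: int, arm_bias: float) -> int:
    """Element start position; arm_bias > 0 enriches chromosome ends."""
    span = chrom_len - length
    while True:
        x = rng.random()
        if arm_bias <= 0:
            break
        accept = (1 + arm_bias * 2 * abs(x - 0.5)) / (1 + arm_bias)
        if rng.random() < accept:
            break
    return int(x * span)


def simulate_annotation_suite(cfg: SimConfig) -> AnnotationSuite:
    """Planted true repeat landscape plus per-tool derived masks.

    True elements never overlap one another (so per-class placed bp is an
    exact density oracle).  Tool masks keep true elements at the tool's sensitivity (partnered
    tools via a shared latent subsample plus flip noise), jitter endpoints and
    add unlabelled false calls.  Raises when a class's density target cannot
    be placed.
    """
    index = cfg.index
    total = index.total_length
    if sum(p.density for p in cfg.class_profiles.values()) > 0.95:
        raise ValueError("total planted density > 0.95 of the genome is infeasible")
    rng = _rng(cfg.seed, "true")
    placer = _Placer()
    chroms = list(cfg.chrom_lengths.items())
    chrom_w = np.array([l for _, l in chroms], dtype=float)
    chrom_w /= chrom_w.sum()

    true_elements: list[RepeatElement] = []
    class_bp: dict[TEClass, int] = {}
    for cls in sorted(cfg.class_profiles, key=lambda c: c.value):
        prof = cfg.class_profiles[cls]
        if prof.density > 0.5:
            raise ValueError(
                f"class {cls.value}: density {prof.density} infeasible without "
                "same-class overlap"
            )
        target_bp = int(prof.density * total)
        sf_names = sorted(prof.superfamilies) if prof.superfamilies else [""]
        sf_w = (
            np.array([prof.superfamilies[s] for s in sf_names], dtype=float)
            if prof.superfamilies
            else np.array([1.0])
        )
        sf_w /= sf_w.sum()
        placed_bp = 0
        attempts = 0
        max_attempts = 200 * max(1, target_bp // prof.mean_length)
        while placed_bp < target_bp:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"class {cls.value}: could not reach density {prof.density} "
                    f"after {attempts} placement attempts"
                )
            length = max(
                prof.min_length, int(rng.gamma(2.0, prof.mean_length / 2.0))
            )
            ci = rng.choice(len(chroms), p=chrom_w)
            chrom, clen = chroms[ci]
            if length >= clen:
                continue
            start = _sample_position(rng, clen, length, prof.arm_bias)
            # true elements never overlap, across classes too, so per-class
            # placed bp is an exact density bookkeeping oracle
            if not placer.try_place(chrom, "all", start, start + length):
                continue
            sf = sf_names[rng.choice(len(sf_names), p=sf_w)] if prof.superfamilies else ""
            true_elements.append(
                RepeatElement(
                    interval=Interval(chrom, start, start + length),
                    te_class=cls,
                    superfamily=sf,
                    source="true",
                )
            )
            placed_bp += length
        class_bp[cls] = placed_bp
    true_elements.sort(key=lambda e: e.interval)
    true_set = RepeatAnnotationSet(source="true", elements=true_elements, index=index)

    # latent subsample per partner pair
    pair_ids = sorted({t.latent_partner for t in cfg.tools if t.latent_partner})
    latent: dict[str, np.ndarray] = {}
    for pid in pair_ids:
        sens = max(
            t.sensitivity for t in cfg.tools if t.latent_partner == pid
        )
        prng = _rng(cfg.seed, "pair", pid)
        latent[pid] = prng.random(len(true_elements)) < sens

    tool_sets: list[RepeatAnnotationSet] = []
    tool_stats: dict[str, dict] = {}
    for tool in cfg.tools:
        trng = _rng(cfg.seed, "tool", tool.name)
        if tool.latent_partner:
            keep = latent[tool.latent_partner] & (
                trng.random(len(true_elements)) >= tool.flip_noise
            )
        else:
            keep = trng.random(len(true_elements)) < tool.sensitivity
        elements: list[RepeatElement] = []
        lengths = dict(cfg.chrom_lengths)
        for el, k in zip(true_elements, keep):
            if not k:
                continue
            iv = el.interval
            if tool.jitter_sd > 0:
                clen = lengths[iv.chrom]
                s = int(round(iv.start + trng.normal(0, tool.jitter_sd)))
                e = int(round(iv.end + trng.normal(0, tool.jitter_sd)))
                s = min(max(s, 0), clen - 1)
                e = min(max(e, s + 1), clen)
                iv = Interval(iv.chrom, s, e)
            elements.append(
                RepeatElement(
                    interval=iv,
                    te_class=el.te_class,
                    superfamily=el.superfamily,
                    source=tool.name,
                )
            )
        n_kept = len(elements)
        fp_target = int(tool.fp_density * total)
        fp_bp = 0
        while fp_bp < fp_target:
            length = max(30, int(trng.gamma(2.0, 150.0)))
            ci = trng.choice(len(chroms), p=chrom_w)
            chrom, clen = chroms[ci]
            if length >= clen:
                continue
            start = int(trng.integers(0, clen - length))
            elements.append(
                RepeatElement(
                    interval=Interval(chrom, start, start + length),
                    te_class=TEClass.UNKNOWN,
                    source=tool.name,
                )
            )
            fp_bp += length
        elements.sort(key=lambda e: e.interval)
        tool_sets.append(
            RepeatAnnotationSet(source=tool.name, elements=elements, index=index)
        )
        tool_stats[tool.name] = {
            "kept_true_elements": n_kept,
            "false_elements": len(elements) - n_kept,
            "false_bp": fp_bp,
            "partner": tool.latent_partner,
        }

    registry = {
        "genome_bp": total,
        "class_bp": {cls.value: bp for cls, bp in class_bp.items()},
        "true_fraction": sum(
            iv.length for iv in merge_intervals(true_set.intervals())
        )
        / total,
        "planted_total_density": sum(p.density for p in cfg.class_profiles.values()),
        "tool_stats": tool_stats,
        "partner_pairs": {
            pid: sorted(t.name for t in cfg.tools if t.latent_partner == pid)
            for pid in pair_ids
        },
    }
    return AnnotationSuite(
        index=index, true_set=true_set, tool_sets=tool_sets, registry=registry
    )


# ---------------------------------------------------------------------------
# gene fixture
# ---------------------------------------------------------------------------


@dataclass
class GeneFixture:
    index: GenomeIndex
    repeats: RepeatAnnotationSet
    se_genes: list[GeneModel]  # single-exon channel (containment analysis)
    annotated_genes: list[GeneModel]  # multi-exon/multi-isoform channel
    registry: pd.DataFrame


def _coverage_by_class(
    exon: Interval, merged: dict[TEClass, list[Interval]]
) -> dict[TEClass, int]:
    return {cls: intersect_length([exon], m) for cls, m in merged.items()}


def simulate_gene_fixture(cfg: SimConfig) -> GeneFixture:
    """Gene models with planted repeat-overlap outcomes.

    Single-exon channel: transcripts fully inside elements of configured
    superfamilies, 1-bp-shortfall transcripts (exon exceeds its element by one
    base), and repeat-free transcripts.  Annotated channel: two-exon genes
    with one exon at coverage exactly 0.5 (inclusive-boundary cases), genes
    just below 0.5, repeat-free genes and multi-isoform genes for merge tests.
    The registry lists the expected outcome of every planted gene.
    """
    suite = simulate_annotation_suite(cfg)
    index, aset = suite.index, suite.true_set
    rng = _rng(cfg.seed, "genes")
    gcfg = cfg.genes
    merged = {cls: aset.merged(cls) for cls in aset.te_classes}
    all_merged = merge_intervals(aset.intervals())
    lengths = index.lengths
    by_sf: dict[tuple[str, str], list[RepeatElement]] = {}
    for el in aset.elements:
        by_sf.setdefault((el.te_class.value, el.superfamily), []).append(el)

    se_genes: list[GeneModel] = []
    annotated: list[GeneModel] = []
    rows: list[dict] = []
    counter = 0

    def new_ids() -> tuple[str, str]:
        nonlocal counter
        counter += 1
        return f"gene{counter:05d}", f"tx{counter:05d}.1"

    def se_gene(exon: Interval) -> GeneModel:
        gid, tid = new_ids()
        return GeneModel(
            gene_id=gid,
            transcripts=(Transcript(transcript_id=tid, exons=(exon,)),),
        )

    def other_classes_clear(exon: Interval, cls: TEClass, limit: float) -> bool:
        """No other class reaches ``limit`` coverage of the exon."""
        for other, cov in _coverage_by_class(exon, merged).items():
            if other != cls and cov >= limit * exon.length:
                return False
        return True

    # --- contained single-exon transcripts -------------------------------
    for (cls_val, sf), n in sorted(gcfg.contained_per_superfamily.items()):
        cls = TEClass(cls_val)
        pool = [e for e in by_sf.get((cls_val, sf), []) if e.interval.length >= 60]
        if not pool:
            raise ValueError(
                f"no elements of {cls_val}/{sf} long enough to host exons; "
                "increase that class's density or length"
            )
        placed = 0
        attempts = 0
        while placed < n:
            attempts += 1
            if attempts > 500 * n:
                raise ValueError(f"could not plant {n} contained exons in {cls_val}/{sf}")
            el = pool[rng.integers(0, len(pool))]
            iv = el.interval
            if rng.random() < 0.3:
                exon = iv  # exon identical to the element
            else:
                L = int(rng.integers(50, iv.length + 1))
                s = int(rng.integers(iv.start, iv.end - L + 1))
                exon = Interval(iv.chrom, s, s + L)
            if not other_classes_clear(exon, cls, 1.0):
                continue
            gene = se_gene(exon)
            se_genes.append(gene)
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "transcript_id": gene.transcripts[0].transcript_id,
                    "kind": "contained",
                    "te_class": cls_val,
                    "superfamily": sf,
                    "chrom": exon.chrom,
                    "start": exon.start,
                    "end": exon.end,
                    "expected_containment": True,
                    "expected_coverage_qualify": False,
                }
            )
            placed += 1

    # --- 1-bp shortfall single-exon transcripts --------------------------
    placed = attempts = 0
    host_elements = [e for e in aset.elements if e.interval.length >= 80]
    while placed < gcfg.n_shortfall:
        attempts += 1
        if attempts > 1000 * max(1, gcfg.n_shortfall):
            raise ValueError("could not plant shortfall exons")
        el = host_elements[rng.integers(0, len(host_elements))]
        iv = el.interval
        if iv.end + 1 > lengths[iv.chrom]:
            continue
        exon = Interval(iv.chrom, iv.start, iv.end + 1)
        cov = _coverage_by_class(exon, merged)
        # one base short of containment in its own class, no other class full
        if cov[el.te_class] != exon.length - 1:
            continue
        if not other_classes_clear(exon, el.te_class, 1.0):
            continue
        gene = se_gene(exon)
        se_genes.append(gene)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "transcript_id": gene.transcripts[0].transcript_id,
                "kind": "contained_shortfall",
                "te_class": el.te_class.value,
                "superfamily": el.superfamily,
                "chrom": exon.chrom,
                "start": exon.start,
                "end": exon.end,
                "expected_containment": False,
                "expected_coverage_qualify": False,
            }
        )
        placed += 1

    def clear_interval(length: int) -> Interval:
        """An interval with zero repeat coverage of any class."""
        for _ in range(10_000):
            ci = rng.integers(0, len(index.entries))
            chrom, clen = index.entries[ci]
            if length >= clen:
                continue
            s = int(rng.integers(0, clen - length))
            iv = Interval(chrom, s, s + length)
            if intersect_length([iv], all_merged) == 0:
                return iv
        raise ValueError("could not find a repeat-free region; genome too dense")

    # --- repeat-free single-exon transcripts -----------------------------
    for _ in range(gcfg.n_clear_se):
        exon = clear_interval(int(rng.integers(100, 400)))
        gene = se_gene(exon)
        se_genes.append(gene)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "transcript_id": gene.transcripts[0].transcript_id,
                "kind": "clear_se",
                "te_class": "",
                "superfamily": "",
                "chrom": exon.chrom,
                "start": exon.start,
                "end": exon.end,
                "expected_containment": False,
                "expected_coverage_qualify": False,
            }
        )

    # --- exactly-half-covered exons in two-exon genes --------------------
    def straddling_exon(target: str) -> tuple[Interval, TEClass, str] | None:
        """Exon straddling an element's right edge at coverage 1/2 ('half') or
        (L/2-1)/L ('below')."""
        el = host_elements[rng.integers(0, len(host_elements))]
        iv = el.interval
        h = int(rng.integers(25, min(200, iv.length) + 1))
        if target == "half":
            s, e = iv.end - h, iv.end + h
        else:
            s, e = iv.end - (h - 1), iv.end + h + 1
        if s < 0 or e > lengths[iv.chrom]:
            return None
        exon = Interval(iv.chrom, s, e)
        want = h if target == "half" else h - 1
        cov = _coverage_by_class(exon, merged)
        if cov[el.te_class] != want:
            return None
        if not other_classes_clear(exon, el.te_class, 0.5):
            return None
        return exon, el.te_class, el.superfamily

    for kind, count in (("half_covered", gcfg.n_half_covered), ("below_half", gcfg.n_below_half)):
        placed = attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 2000 * max(1, count):
                raise ValueError(f"could not plant {kind} exons")
            got = straddling_exon("half" if kind == "half_covered" else "below")
            if got is None:
                continue
            exon, cls, sf = got
            exon2 = clear_interval(int(rng.integers(100, 300)))
            if exon2.overlaps(exon):
                continue
            gid, tid = new_ids()
            exons = tuple(sorted((exon, exon2)))
            annotated.append(
                GeneModel(
                    gene_id=gid,
                    transcripts=(Transcript(transcript_id=tid, exons=(exons[0],)),
                                 Transcript(transcript_id=tid + "b", exons=(exons[1],))),
                )
            )
            rows.append(
                {
                    "gene_id": gid,
                    "transcript_id": tid,
                    "kind": kind,
                    "te_class": cls.value,
                    "superfamily": sf,
                    "chrom": exon.chrom,
                    "start": exon.start,
                    "end": exon.end,
                    "expected_containment": False,
                    "expected_coverage_qualify": kind == "half_covered",
                }
            )
            placed += 1

    # --- repeat-free multi-exon genes ------------------------------------
    placed = 0
    while placed < gcfg.n_clear_multi:
        e1 = clear_interval(int(rng.integers(100, 300)))
        e2 = clear_interval(int(rng.integers(100, 300)))
        if e1.overlaps(e2):
            continue
        placed += 1
        gid, tid = new_ids()
        annotated.append(
            GeneModel(
                gene_id=gid,
                transcripts=(Transcript(transcript_id=tid, exons=tuple(sorted((e1, e2)))),),
            )
        )
        rows.append(
            {
                "gene_id": gid,
                "transcript_id": tid,
                "kind": "clear_multi",
                "te_class": "",
                "superfamily": "",
                "chrom": e1.chrom,
                "start": e1.start,
                "end": e1.end,
                "expected_containment": False,
                "expected_coverage_qualify": False,
            }
        )

    # --- multi-isoform genes (merge channel) ------------------------------
    for _ in range(gcfg.n_multi_isoform):
        base = clear_interval(400)
        mid = base.start + 200
        gid, tid = new_ids()
        iso1 = Transcript(transcript_id=tid, exons=(Interval(base.chrom, base.start, mid),))
        iso2 = Transcript(
            transcript_id=tid.replace(".1", ".2"),
            exons=(Interval(base.chrom, base.start + 100, base.end),),
        )
        annotated.append(GeneModel(gene_id=gid, transcripts=(iso1, iso2)))
        rows.append(
            {
                "gene_id": gid,
                "transcript_id": tid,
                "kind": "isoform_merge",
                "te_class": "",
                "superfamily": "",
                "chrom": base.chrom,
                "start": base.start,
                "end": base.end,
                "expected_containment": False,
                "expected_coverage_qualify": False,
            }
        )

    registry = pd.DataFrame(rows)
    return GeneFixture(
        index=index,
        repeats=aset,
        se_genes=se_genes,
        annotated_genes=annotated,
        registry=registry,
    )


# ---------------------------------------------------------------------------
# hit table / labels / gene orders
# ---------------------------------------------------------------------------


@dataclass
class HitTableFixture:
    hit_table: HitTable
    true_classes: pd.Series  # realized age class per gene (max hit index)
    overlap_map: dict[str, set[TEClass]]
    registry: pd.DataFrame  # per (age_class, te_class) planted counts/fractions


def simulate_hit_table(cfg: SimConfig) -> HitTableFixture:
    """Boolean hit table over the species ladder plus a planted overlap map.

    Rows are monotone up to the drawn age class (hit at the defining species,
    nearer species hit at ``near_hit_prob``) with optional sporadic more
    distant hits; the registry records the *realized* class of every gene (the
    max hit index), so it stays correct when sporadic hits promote a gene.
    Overlap counts per (class, repeat type) are planted exactly as
    ``round(fraction * class size)`` of the realized strata.
    """
    hcfg = cfg.hits
    K = len(hcfg.species)
    props = np.asarray(hcfg.proportions, dtype=float)
    if len(props) != K + 1:
        raise ValueError(f"need {K + 1} age-class proportions, got {len(props)}")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("age-class proportions must sum to 1")
    rng = _rng(cfg.seed, "hits")
    drawn = rng.choice(K + 1, size=hcfg.n_genes, p=props)
    genes = [f"g{i:05d}" for i in range(hcfg.n_genes)]
    mat = np.zeros((hcfg.n_genes, K), dtype=bool)
    for i, k in enumerate(drawn):
        if k > 0:
            mat[i, k - 1] = True
            mat[i, : k - 1] = rng.random(k - 1) < hcfg.near_hit_prob
        if hcfg.sporadic_rate > 0 and k < K:
            mat[i, k:] |= rng.random(K - k) < hcfg.sporadic_rate
    ht = HitTable(
        species_order=tuple(hcfg.species),
        hits=pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=list(hcfg.species)),
    )
    idx = np.arange(1, K + 1)
    realized = np.where(mat.any(axis=1), (mat * idx).max(axis=1), 0)
    true_classes = pd.Series(realized, index=ht.hits.index, name="age_class")

    overlap_map: dict[str, set[TEClass]] = {}
    reg_rows = []
    for age in range(K + 1):
        members = np.flatnonzero(realized == age)
        size = len(members)
        for cls in sorted(hcfg.overlap_fractions, key=lambda c: c.value):
            frac = hcfg.overlap_fractions[cls][age]
            n = int(round(frac * size))
            chosen = rng.choice(members, size=n, replace=False) if n else []
            for gi in chosen:
                overlap_map.setdefault(genes[gi], set()).add(cls)
            reg_rows.append(
                {
                    "age_class": age,
                    "te_class": cls.value,
                    "n_genes": size,
                    "n_overlapping": n,
                    "fraction": (n / size) if size else float("nan"),
                }
            )
    registry = pd.DataFrame(
        reg_rows, columns=["age_class", "te_class", "n_genes", "n_overlapping", "fraction"]
    )
    return HitTableFixture(
        hit_table=ht, true_classes=true_classes, overlap_map=overlap_map, registry=registry
    )


@dataclass
class LabelFixture:
    label_table: LabelTable
    truth: pd.Series  # class-level truth per element
    registry: pd.DataFrame  # per-method planted and realized flip rates


_DNA_ORDERS = ("DNA", "RC")
_RETRO_ORDERS = ("LINE", "LTR", "Penelope", "SINE")


def simulate_labels(cfg: SimConfig) -> LabelFixture:
    """Three-classifier label table with planted per-method class flip rates.

    Truth is a DNA-transposon/retrotransposon mix with an order-level detail
    label; each method reports the truth order unless flipped (probability =
    its flip rate), in which case it reports a random order of the opposite
    class; an optional ``unknown_rate`` replaces labels with 'Unknown'.
    """
    lcfg = cfg.labels
    if len(lcfg.methods) != len(lcfg.flip_rates):
        raise ValueError("one flip rate per method required")
    rng = _rng(cfg.seed, "labels")
    n = lcfg.n_elements
    elements = [f"te{i:05d}" for i in range(n)]
    is_retro = rng.random(n) < lcfg.retro_fraction
    truth_orders = np.where(
        is_retro,
        rng.choice(_RETRO_ORDERS, size=n),
        rng.choice(_DNA_ORDERS, size=n),
    )
    truth = pd.Series(
        np.where(is_retro, CLASS_RETRO, CLASS_DNA),
        index=pd.Index(elements, name="element_id"),
        name="truth",
    )
    data = {}
    reg_rows = []
    for method, rate in zip(lcfg.methods, lcfg.flip_rates):
        flips = rng.random(n) < rate
        labels = truth_orders.copy()
        flipped_dna = flips & is_retro
        flipped_retro = flips & ~is_retro
        labels[flipped_dna] = rng.choice(_DNA_ORDERS, size=int(flipped_dna.sum()))
        labels[flipped_retro] = rng.choice(_RETRO_ORDERS, size=int(flipped_retro.sum()))
        if lcfg.unknown_rate > 0:
            unknown = rng.random(n) < lcfg.unknown_rate
            labels[unknown] = "Unknown"
            flips = flips | unknown
        data[method] = labels
        reg_rows.append(
            {
                "method": method,
                "planted_flip_rate": rate,
                "realized_flip_rate": float(flips.mean()),
                "n_flipped": int(flips.sum()),
            }
        )
    lt = LabelTable(
        orders=pd.DataFrame(data, index=pd.Index(elements, name="element_id"))
    )
    registry = pd.DataFrame(
        reg_rows, columns=["method", "planted_flip_rate", "realized_flip_rate", "n_flipped"]
    )
    return LabelFixture(label_table=lt, truth=truth, registry=registry)


@dataclass
class GeneOrderFixture:
    focal: GeneOrder
    out1: GeneOrder
    out2: GeneOrder
    registry: pd.DataFrame  # one row per planted insertion
    target_family: str


def _local_shuffle(rng: np.random.Generator, seq: list, rate: float) -> list:
    """One pass of adjacent transpositions at the given per-position rate."""
    seq = list(seq)
    for i in range(len(seq) - 1):
        if rng.random() < rate:
            seq[i], seq[i + 1] = seq[i + 1], seq[i]
    return seq


def simulate_gene_orders(cfg: SimConfig) -> GeneOrderFixture:
    """Three-species gene orders from a shared ancestral order.

    Each species order is a locally shuffled copy of the ancestral family
    sequence (adjacent swaps at ``shuffle_rate``); the focal species
    additionally carries ``n_insertions`` planted genes of the target family.
    Some ancestral families are duplicated (never anchors) and some tokens are
    hidden as UNASSIGNED per species.  The registry lists every planted gene
    with its ancestral flanking families.
    """
    ocfg = cfg.orders
    rng = _rng(cfg.seed, "orders")
    focal_sp, out1_sp, out2_sp = ocfg.species
    scaffolds = {sp: {} for sp in ocfg.species}
    reg_rows = []
    ins_counter = 0
    for si in range(ocfg.n_scaffolds):
        sc = f"scaffold{si + 1}"
        fams = [f"F{si + 1}_{i:04d}" for i in range(ocfg.families_per_scaffold)]
        # duplicate some families (multi-copy: excluded from anchoring)
        for f in list(fams):
            if rng.random() < ocfg.dup_rate:
                fams.insert(int(rng.integers(0, len(fams) + 1)), f)
        per_species: dict[str, list[tuple[str, str]]] = {}
        for sp in ocfg.species:
            order = _local_shuffle(rng, fams, ocfg.shuffle_rate)
            genes = []
            for j, fam in enumerate(order):
                shown = fam
                if rng.random() < ocfg.unassigned_rate:
                    shown = UNASSIGNED
                genes.append((f"{sp}_{sc}_g{j:04d}", shown))
            per_species[sp] = genes
        # plant focal insertions away from scaffold edges
        n_ins = ocfg.n_insertions // ocfg.n_scaffolds + (
            1 if si < ocfg.n_insertions % ocfg.n_scaffolds else 0
        )
        focal_genes = per_species[focal_sp]
        positions = sorted(
            rng.choice(
                np.arange(3, len(focal_genes) - 3), size=n_ins, replace=False
            ),
            reverse=True,
        )
        for pos in positions:
            ins_counter += 1
            gid = f"{focal_sp}_{sc}_zis{ins_counter:03d}"
            left, right = focal_genes[pos - 1][1], focal_genes[pos][1]
            focal_genes.insert(int(pos), (gid, ocfg.target_family))
            reg_rows.append(
                {
                    "gene_id": gid,
                    "scaffold": sc,
                    "family": ocfg.target_family,
                    "left_neighbor": left,
                    "right_neighbor": right,
                }
            )
        if ocfg.reverse_out2:
            per_species[out2_sp] = per_species[out2_sp][::-1]
        for sp in ocfg.species:
            scaffolds[sp][sc] = per_species[sp]
    return GeneOrderFixture(
        focal=GeneOrder(species=focal_sp, scaffolds=scaffolds[focal_sp]),
        out1=GeneOrder(species=out1_sp, scaffolds=scaffolds[out1_sp]),
        out2=GeneOrder(species=out2_sp, scaffolds=scaffolds[out2_sp]),
        registry=pd.DataFrame(
            reg_rows,
            columns=["gene_id", "scaffold", "family", "left_neighbor", "right_neighbor"],
        ),
        target_family=ocfg.target_family,
    )
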