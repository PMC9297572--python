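"""Interval algebra, windowing and flat-file IO round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_set, random_intervals
from oracles import (
    covered_fraction as oracle_coverage,
    intersect_bases as oracle_intersect,
    mask_array,
    masked_bases as oracle_masked,
    merged_from_array,
)
from repeatconcord.genomic_intervals import (
    BedParseError,
    GenomeIndex,
    Interval,
    RepeatAnnotationSet,
    RepeatElement,
    TEClass,
    ValidationError,
    coverage_fraction,
    format_repeat_name,
    intersect_length,
    make_windows,
    merge_intervals,
    parse_repeat_name,
    read_bed,
    read_genome_index,
    read_gff3_genes,
    total_masked_bases,
    window_coverage_bases,
    write_bed,
    write_genome_index,
    write_gff3_genes,
)


class TestInterval:
    def test_rejects_degenerate_coordinates(self):
        with pytest.raises(ValidationError):
            Interval("c1", 5, 5)
        with pytest.raises(ValidationError):
            Interval("c1", -1, 4)
        with pytest.raises(ValidationError):
            Interval("c1", 10, 4)

    def test_length_is_half_open(self):
        assert Interval("c1", 0, 100).length == 100

    def test_index_validation_rejects_overhang(self, small_index):
        with pytest.raises(ValidationError, match="extends past"):
            small_index.validate_interval(Interval("chr1", 9_500, 10_001))
        with pytest.raises(ValidationError, match="unknown chromosome"):
            small_index.validate_interval(Interval("chrZ", 0, 10))


class TestMakeWindows:
    @pytest.mark.parametrize(
        "lengths,w,expected",
        [
            ({"c1": 2500}, 1000, [(0, 1000), (1000, 2000), (2000, 2500)]),
            ({"c1": 1000}, 1000, [(0, 1000)]),
            ({"c1": 1500, "c2": 500}, 1000, [(0, 1000), (1000, 1500), (0, 500)]),
        ],
    )
    def test_tiling_with_partial_tail(self, lengths, w, expected):
        index = GenomeIndex(entries=tuple(lengths.items()))
        grid = make_windows(index, w)
        assert [(x.start, x.end) for x in grid.windows] == expected

    def test_rejects_nonpositive_window(self, small_index):
        with pytest.raises(ValueError):
            make_windows(small_index, 0)

    @given(st.lists(st.integers(1, 5000), min_size=1, max_size=5), st.integers(1, 700))
    @settings(derandomize=True, max_examples=50)
    def test_tiling_conserves_genome_length(self, lengths, w):
        index = GenomeIndex(
            entries=tuple((f"c{i}", l) for i, l in enumerate(lengths))
        )
        grid = make_windows(index, w)
        assert int(grid.window_lengths().sum()) == index.total_length


class TestMergeIntervals:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([("c1", 0, 10), ("c1", 5, 15)], [("c1", 0, 15)]),
            ([("c1", 0, 10), ("c1", 10, 20)], [("c1", 0, 20)]),  # touching merge
            ([("c1", 0, 10), ("c2", 0, 10)], [("c1", 0, 10), ("c2", 0, 10)]),
        ],
    )
    def test_examples(self, raw, expected):
        merged = merge_intervals(Interval(*t) for t in raw)
        assert [(i.chrom, i.start, i.end) for i in merged] == expected

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ivs = random_intervals(rng, {"c1": 5000})
        once = merge_intervals(ivs)
        assert merge_intervals(once) == once


class TestIntersectAndCoverage:
    def test_worked_examples(self):
        a, b = [Interval("c1", 0, 100)], [Interval("c1", 50, 150)]
        assert intersect_length(a, b) == 50
        assert intersect_length(a, [Interval("c1", 200, 300)]) == 0
        assert intersect_length(a, a) == 100

    def test_commutative(self):
        rng = np.random.default_rng(1)
        a = random_intervals(rng, {"c1": 3000, "c2": 2000})
        b = random_intervals(rng, {"c1": 3000, "c2": 2000})
        assert intersect_length(a, b) == intersect_length(b, a)

    def test_coverage_examples(self):
        exon = Interval("c1", 100, 200)
        assert coverage_fraction(exon, [Interval("c1", 100, 150)]) == 0.5
        assert coverage_fraction(exon, [Interval("c1", 0, 500)]) == 1.0
        # overlapping mask pieces must be merged before counting
        mask = [Interval("c1", 90, 120), Interval("c1", 110, 160)]
        assert coverage_fraction(exon, mask) == 0.6

    def test_coverage_monotone_under_mask_growth(self):
        rng = np.random.default_rng(2)
        target = Interval("c1", 400, 900)
        mask: list[Interval] = []
        last = 0.0
        for iv in random_intervals(rng, {"c1": 2000}, n_max=30):
            mask.append(iv)
            frac = coverage_fraction(target, mask)
            assert frac >= last - 1e-12
            last = frac


class TestTotalMaskedBases:
    def test_dedup_and_disjoint(self):
        dis = make_set([Interval("c1", 0, 100), Interval("c1", 200, 300)])
        assert total_masked_bases(dis) == 200
        dup = make_set([Interval("c1", 0, 100), Interval("c1", 0, 100)])
        assert total_masked_bases(dup) == 100

    def test_invariant_under_splitting(self):
        rng = np.random.default_rng(3)
        ivs = random_intervals(rng, {"c1": 4000})
        whole = total_masked_bases(make_set(ivs))
        split = []
        for iv in ivs:
            if iv.length > 1:
                mid = iv.start + iv.length // 2
                split += [Interval(iv.chrom, iv.start, mid), Interval(iv.chrom, mid, iv.end)]
            else:
                split.append(iv)
        assert total_masked_bases(make_set(split)) == whole


@given(st.integers(0, 10_000))
@settings(derandomize=True, max_examples=300)
def test_algebra_matches_per_base_oracle(seed):
    """merge/intersect/coverage/total agree exactly with boolean-array oracles
    on random small genomes."""
    rng = np.random.default_rng(seed)
    lens = {
        f"c{i}": int(rng.integers(200, 10_001))
        for i in range(int(rng.integers(1, 4)))
    }
    a = random_intervals(rng, lens)
    b = random_intervals(rng, lens)
    assert total_masked_bases(make_set(a)) == oracle_masked(a, lens)
    assert intersect_length(a, b) == oracle_intersect(a, b, lens)
    merged = merge_intervals(a)
    assert [(i.chrom, i.start, i.end) for i in merged] == merged_from_array(
        mask_array(a, lens)
    )
    chrom = list(lens)[0]
    tlen = min(500, lens[chrom])
    target = Interval(chrom, 0, tlen)
    assert coverage_fraction(target, a) == pytest.approx(
        oracle_coverage(target, a, lens), abs=0
    )


def test_window_coverage_bases_conserves_mask():
    rng = np.random.default_rng(4)
    index = GenomeIndex(entries=(("c1", 7341), ("c2", 2000)))
    ivs = random_intervals(rng, index.lengths)
    grid = make_windows(index, 500)
    per_window = window_coverage_bases(ivs, grid)
    assert int(per_window.sum()) == oracle_masked(ivs, index.lengths)


class TestIO:
    def test_genome_index_round_trip(self, tmp_path, small_index):
        p = tmp_path / "idx.tsv"
        write_genome_index(small_index, p)
        assert read_genome_index(p) == small_index

    def test_repeat_name_conventions(self):
        assert parse_repeat_name("LINE/CR1") == (TEClass.LINE, "CR1")
        assert parse_repeat_name("RC/Helitron") == (TEClass.RC_HELITRON, "Helitron")
        assert parse_repeat_name("Simple_repeat") == (TEClass.SIMPLE_REPEAT, "")
        assert format_repeat_name(TEClass.LINE, "CR1") == "LINE/CR1"

    def test_bed_round_trip(self, tmp_path, small_index):
        rng = np.random.default_rng(5)
        classes = [TEClass.LINE, TEClass.DNA, TEClass.SIMPLE_REPEAT]
        sfs = {TEClass.LINE: "CR1", TEClass.DNA: "Sola-3", TEClass.SIMPLE_REPEAT: ""}
        elements = [
            RepeatElement(interval=iv, te_class=c, superfamily=sfs[c], source="rm2")
            for iv, c in zip(
                random_intervals(rng, small_index.lengths, n_max=50),
                (classes[i] for i in rng.integers(0, len(classes), 50)),
            )
        ]
        aset = RepeatAnnotationSet(source="rm2", elements=elements, index=small_index)
        p = tmp_path / "rm2.bed"
        write_bed(aset, p)
        back = read_bed(p, source="rm2", index=small_index)
        assert back.elements == aset.elements

    def test_bed_parse_and_validation_errors(self, tmp_path, small_index):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\tNaN\tLINE/CR1\n")
        with pytest.raises(BedParseError, match=":1:"):
            read_bed(p)
        p.write_text("chr1\t0\t999999\tLINE/CR1\n")
        with pytest.raises(ValidationError, match="extends past"):
            read_bed(p, index=small_index)

    def test_gff3_coordinates_converted(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n"
            "chr1\t.\tmRNA\t101\t200\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\t.\texon\t101\t200\t.\t+\t.\tID=t1.e1;Parent=t1\n"
        )
        genes = read_gff3_genes(gff)
        exon = genes[0].transcripts[0].exons[0]
        assert (exon.start, exon.end) == (100, 200)

    def test_gff3_round_trip(self, tmp_path):
        from repeatconcord.gene_overlap import GeneModel, Transcript

        genes = [
            GeneModel(
                gene_id="gA",
                transcripts=(
                    Transcript("tA.1", (Interval("chr1", 10, 50), Interval("chr1", 80, 120)), "+"),
                    Transcript("tA.2", (Interval("chr1", 10, 120),), "+"),
                ),
            )
        ]
        p = tmp_path / "rt.gff3"
        write_gff3_genes(genes, p)
        back = read_gff3_genes(p)
        assert back == genes
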