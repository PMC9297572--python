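"""Isoform merging, containment and fractional-coverage overlap rules."""

import pytest

from repeatconcord.gene_overlap import (
    GeneModel,
    Transcript,
    exon_coverage_overlaps,
    fully_contained_overlaps,
    gene_class_map,
    merge_isoforms,
    superfamily_tally,
)
from repeatconcord.genomic_intervals import (
    Interval,
    RepeatAnnotationSet,
    RepeatElement,
    TEClass,
)
from repeatconcord.synthetic_data import SimConfig, simulate_gene_fixture


def se_gene(gid, chrom, start, end):
    return GeneModel(
        gene_id=gid,
        transcripts=(Transcript(f"{gid}.t1", (Interval(chrom, start, end),)),),
    )


def repeat_set(*specs):
    """specs: (chrom, start, end, cls, superfamily)"""
    return RepeatAnnotationSet(
        source="rm2",
        elements=[
            RepeatElement(
                interval=Interval(c, s, e), te_class=cls, superfamily=sf, source="rm2"
            )
            for c, s, e, cls, sf in specs
        ],
    )


class TestMergeIsoforms:
    def test_overlapping_isoform_exons_union(self):
        gene = GeneModel(
            gene_id="g",
            transcripts=(
                Transcript("t1", (Interval("c1", 0, 100),)),
                Transcript("t2", (Interval("c1", 50, 150),)),
            ),
        )
        merged = merge_isoforms([gene])[0]
        assert len(merged.transcripts) == 1
        assert merged.transcripts[0].exons == (Interval("c1", 0, 150),)

    def test_single_isoform_exons_unchanged(self):
        gene = se_gene("g", "c1", 10, 90)
        assert merge_isoforms([gene])[0].transcripts[0].exons == (Interval("c1", 10, 90),)

    def test_disjoint_exons_retained(self):
        gene = GeneModel(
            gene_id="g",
            transcripts=(
                Transcript("t1", (Interval("c1", 0, 100),)),
                Transcript("t2", (Interval("c1", 200, 300),)),
            ),
        )
        assert merge_isoforms([gene])[0].transcripts[0].exons == (
            Interval("c1", 0, 100),
            Interval("c1", 200, 300),
        )


class TestFullContainment:
    @pytest.mark.parametrize(
        "el_span,contained",
        [((100, 200), True), ((90, 210), True), ((100, 199), False)],
    )
    def test_boundary_cases(self, el_span, contained):
        aset = repeat_set(("c1", *el_span, TEClass.LINE, "CR1"))
        recs = fully_contained_overlaps([se_gene("g", "c1", 100, 200)], aset)
        assert bool(recs) is contained
        if contained:
            assert recs[0].covered_fraction == 1.0
            assert recs[0].superfamily == "CR1"

    def test_multi_exon_input_rejected(self):
        gene = GeneModel(
            gene_id="g",
            transcripts=(
                Transcript("t", (Interval("c1", 0, 50), Interval("c1", 100, 150))),
            ),
        )
        with pytest.raises(ValueError, match="single-exon"):
            fully_contained_overlaps([gene], repeat_set())

    def test_merged_mask_spans_fragmented_element(self):
        # abutting fragments of the same class still contain the exon
        aset = repeat_set(
            ("c1", 100, 150, TEClass.LINE, "CR1"),
            ("c1", 150, 200, TEClass.LINE, "CR1"),
        )
        recs = fully_contained_overlaps([se_gene("g", "c1", 100, 200)], aset)
        assert len(recs) == 1
        # raw-element mode reproduces the single-element behaviour: no call
        assert (
            fully_contained_overlaps([se_gene("g", "c1", 100, 200)], aset, raw_elements=True)
            == []
        )

    def test_superfamily_attributed_to_largest_overlap(self):
        aset = repeat_set(
            ("c1", 100, 180, TEClass.LINE, "CR1"),
            ("c1", 180, 220, TEClass.LINE, "RTE"),
        )
        recs = fully_contained_overlaps([se_gene("g", "c1", 100, 200)], aset)
        assert recs[0].superfamily == "CR1"
        assert recs[0].tied_superfamilies == ("CR1",)

    def test_superfamily_tie_lexicographic_with_secondary_field(self):
        aset = repeat_set(
            ("c1", 100, 150, TEClass.LINE, "RTE"),
            ("c1", 150, 200, TEClass.LINE, "CR1"),
        )
        recs = fully_contained_overlaps([se_gene("g", "c1", 100, 200)], aset)
        assert recs[0].superfamily == "CR1"
        assert recs[0].tied_superfamilies == ("CR1", "RTE")


class TestExonCoverage:
    def test_inclusive_half_boundary(self):
        aset = repeat_set(("c1", 0, 50, TEClass.DNA, "Sola-3"))
        recs = exon_coverage_overlaps([se_gene("g", "c1", 0, 100)], aset)
        assert len(recs) == 1 and recs[0].covered_fraction == 0.5

    def test_one_bp_below_half_excluded(self):
        aset = repeat_set(("c1", 0, 49, TEClass.DNA, "Sola-3"))
        assert exon_coverage_overlaps([se_gene("g", "c1", 0, 100)], aset) == []

    def test_gene_qualifies_via_any_exon(self):
        gene = GeneModel(
            gene_id="g",
            transcripts=(
                Transcript("t", (Interval("c1", 0, 100), Interval("c1", 200, 300))),
            ),
        )
        aset = repeat_set(("c1", 200, 260, TEClass.LINE, "CR1"))  # 0.6 of exon 2
        recs = exon_coverage_overlaps([gene], aset)
        assert [r.exon.start for r in recs] == [200]
        assert gene_class_map(recs) == {"g": {TEClass.LINE}}

    def test_containment_consistency_with_min_frac_one(self):
        """On single-exon input, coverage at min_frac=1.0 and full containment
        select the same records."""
        fx = simulate_gene_fixture(SimConfig(seed=13))
        contained = fully_contained_overlaps(fx.se_genes, fx.repeats)
        frac_one = exon_coverage_overlaps(fx.se_genes, fx.repeats, min_frac=1.0)
        key = lambda rs: {(r.gene_id, r.te_class, r.exon) for r in rs}
        assert key(contained) == key(frac_one)

    def test_invariant_under_element_splitting(self):
        aset = repeat_set(("c1", 0, 60, TEClass.DNA, "Sola-3"))
        split = repeat_set(
            ("c1", 0, 30, TEClass.DNA, "Sola-3"),
            ("c1", 30, 60, TEClass.DNA, "Sola-3"),
        )
        gene = se_gene("g", "c1", 0, 100)
        a = exon_coverage_overlaps([gene], aset)
        b = exon_coverage_overlaps([gene], split)
        assert [(r.gene_id, r.te_class, r.covered_fraction) for r in a] == [
            (r.gene_id, r.te_class, r.covered_fraction) for r in b
        ]


class TestSuperfamilyTally:
    def _records(self, counts):
        recs = []
        for i, ((cls, sf), n) in enumerate(counts.items()):
            for j in range(n):
                recs.extend(
                    fully_contained_overlaps(
                        [se_gene(f"g{i}_{j}", "c1", 100, 200)],
                        repeat_set(("c1", 100, 200, cls, sf)),
                    )
                )
        return recs

    def test_threshold_inclusive(self):
        recs = self._records(
            {(TEClass.LINE, "CR1"): 35, (TEClass.DNA, "Sola-3"): 25, (TEClass.LINE, "Vingi"): 5}
        )
        df = superfamily_tally(recs, min_count=20)
        assert df.set_index("superfamily")["n_transcripts"].to_dict() == {
            "CR1": 35,
            "Sola-3": 25,
        }

    def test_all_below_threshold_empty(self):
        recs = self._records({(TEClass.LINE, "CR1"): 3})
        assert superfamily_tally(recs, min_count=20).empty

    def test_transcript_counted_once_per_superfamily(self):
        aset = repeat_set(
            ("c1", 100, 160, TEClass.LINE, "CR1"),
            ("c1", 160, 220, TEClass.LINE, "CR1"),
        )
        recs = fully_contained_overlaps([se_gene("g", "c1", 100, 200)], aset)
        df = superfamily_tally(recs, min_count=1)
        assert df["n_transcripts"].tolist() == [1]
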