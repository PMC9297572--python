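"""Presence-matrix construction, method clustering, patterns and agreement."""

import math

import numpy as np
import pytest

from conftest import make_set, random_intervals
from oracles import complete_linkage, window_hit_counts
from repeatconcord.concordance import (
    PresenceMatrix,
    binarize_windows,
    cluster_methods,
    coverage_summary,
    pairwise_agreement,
    pattern_abundance,
)
from repeatconcord.genomic_intervals import (
    GenomeIndex,
    Interval,
    make_windows,
)
from repeatconcord.synthetic_data import SimConfig, simulate_annotation_suite


def grid_for(lengths: dict[str, int], w: int):
    return make_windows(GenomeIndex(entries=tuple(lengths.items())), w)


class TestBinarize:
    def test_single_element_marks_single_window(self):
        grid = grid_for({"c1": 3000}, 1000)
        pm = binarize_windows([make_set([Interval("c1", 1500, 1600)])], grid)
        assert pm.values[:, 0].tolist() == [0, 1, 0]

    def test_boundary_spanning_element_marks_both_windows(self):
        grid = grid_for({"c1": 3000}, 1000)
        pm = binarize_windows([make_set([Interval("c1", 999, 1001)])], grid)
        assert pm.values[:, 0].tolist() == [1, 1, 0]

    def test_empty_set_gives_zero_column(self):
        grid = grid_for({"c1": 3000}, 1000)
        pm = binarize_windows([make_set([])], grid)
        assert pm.values.sum() == 0

    def test_min_bases_threshold(self):
        grid = grid_for({"c1": 2000}, 1000)
        pm = binarize_windows(
            [make_set([Interval("c1", 0, 10)])], grid, min_bases=50
        )
        assert pm.values[:, 0].tolist() == [0, 0]

    def test_column_counts_match_per_base_oracle(self):
        lens = {"c1": 9137, "c2": 4000}
        grid = grid_for(lens, 1000)
        rng = np.random.default_rng(7)
        for _ in range(20):
            ivs = random_intervals(rng, lens)
            pm = binarize_windows([make_set(ivs)], grid)
            assert int(pm.values[:, 0].sum()) == window_hit_counts(ivs, lens, 1000)


class TestClusterMethods:
    def test_identical_columns_merge_at_zero(self):
        grid = grid_for({"c1": 3000}, 1000)
        ivs = [Interval("c1", 100, 300)]
        pm = binarize_windows(
            [make_set(ivs, source="a"), make_set(ivs, source="b")], grid
        )
        dendro = cluster_methods(pm)
        assert dendro.merge_events[0][2] == 0.0

    def test_closed_form_euclidean_height(self):
        # columns (0,0,0) vs (1,1,1) over 3 windows -> sqrt(3)
        grid = grid_for({"c1": 3000}, 1000)
        pm = binarize_windows(
            [make_set([], source="a"), make_set([Interval("c1", 0, 3000)], source="b")],
            grid,
        )
        assert cluster_methods(pm).merge_events[0][2] == pytest.approx(math.sqrt(3))

    def test_requires_two_methods(self):
        grid = grid_for({"c1": 2000}, 1000)
        pm = binarize_windows([make_set([])], grid)
        with pytest.raises(ValueError):
            cluster_methods(pm)

    def test_matches_exhaustive_agglomeration_oracle(self):
        suite = simulate_annotation_suite(SimConfig(seed=42))
        grid = make_windows(suite.index, 1000)
        pm = binarize_windows(suite.tool_sets, grid)
        dendro = cluster_methods(pm)
        order = sorted(range(len(pm.methods)), key=lambda i: pm.methods[i])
        names = [pm.methods[i] for i in order]
        oracle = complete_linkage(names, pm.values[:, order].T)
        assert len(dendro.merge_events) == len(oracle)
        for (a, b, h), (oa, ob, oh) in zip(dendro.merge_events, oracle):
            assert {a, b} == {oa, ob}
            assert h == pytest.approx(oh)

    def test_planted_pairs_merge_first(self):
        suite = simulate_annotation_suite(SimConfig(seed=0))
        grid = make_windows(suite.index, 1000)
        dendro = cluster_methods(binarize_windows(suite.tool_sets, grid))
        for pair in suite.registry["partner_pairs"].values():
            a, b = pair
            assert dendro.first_merge_partners(a) == frozenset({b})

    def test_permutation_invariant(self):
        suite = simulate_annotation_suite(SimConfig(seed=1))
        grid = make_windows(suite.index, 1000)
        pm = binarize_windows(suite.tool_sets, grid)
        pm_rev = binarize_windows(suite.tool_sets[::-1], grid)
        assert cluster_methods(pm).merge_events == cluster_methods(pm_rev).merge_events

    def test_heights_nondecreasing(self):
        suite = simulate_annotation_suite(SimConfig(seed=2))
        grid = make_windows(suite.index, 1000)
        heights = [
            h
            for _, _, h in cluster_methods(
                binarize_windows(suite.tool_sets, grid)
            ).merge_events
        ]
        assert heights == sorted(heights)


class TestPatternAbundance:
    def test_all_zero_pattern_excluded(self):
        grid = grid_for({"c1": 8000}, 1000)
        values = np.zeros((8, 3), dtype=np.int8)
        values[0] = values[1] = (1, 1, 0)
        values[2] = (0, 0, 1)
        pm = PresenceMatrix(grid=grid, methods=("a", "b", "c"), values=values)
        top = pattern_abundance(pm, top_k=2)
        assert [(p.pattern, p.count) for p in top] == [((1, 1, 0), 2), ((0, 0, 1), 1)]

    def test_single_method(self):
        grid = grid_for({"c1": 4000}, 1000)
        pm = PresenceMatrix(
            grid=grid, methods=("a",), values=np.ones((4, 1), dtype=np.int8)
        )
        assert [(p.pattern, p.count) for p in pattern_abundance(pm)] == [((1,), 4)]

    def test_matches_dictionary_count_oracle(self):
        rng = np.random.default_rng(11)
        grid = grid_for({"c1": 1_000_000}, 1000)
        values = (rng.random((1000, 4)) < 0.3).astype(np.int8)
        pm = PresenceMatrix(grid=grid, methods=("a", "b", "c", "d"), values=values)
        from collections import Counter

        oracle = Counter(map(tuple, values.tolist()))
        oracle.pop((0, 0, 0, 0), None)
        got = pattern_abundance(pm, top_k=1000)
        assert {p.pattern: p.count for p in got} == dict(oracle)
        counts = [p.count for p in got]
        assert counts == sorted(counts, reverse=True)


class TestPairwiseAgreement:
    def test_identities(self):
        a = make_set([Interval("c1", 0, 100)], source="a")
        ref_super = make_set([Interval("c1", 0, 500)], source="r")
        assert pairwise_agreement(a, a) == 1.0
        assert pairwise_agreement(a, ref_super) == 1.0
        disjoint = make_set([Interval("c1", 900, 950)], source="d")
        assert pairwise_agreement(a, disjoint) == 0.0

    def test_worked_half_overlap(self):
        a = make_set([Interval("c1", 0, 100)], source="a")
        ref = make_set([Interval("c1", 50, 150)], source="r")
        assert pairwise_agreement(a, ref) == 0.5

    def test_asymmetric_by_design(self):
        sub = make_set([Interval("c1", 0, 100)], source="sub")
        sup = make_set([Interval("c1", 0, 400)], source="sup")
        assert pairwise_agreement(sub, sup) == 1.0
        assert pairwise_agreement(sup, sub) == 0.25

    def test_empty_compared_set_raises(self):
        a = make_set([], source="empty")
        ref = make_set([Interval("c1", 0, 10)], source="r")
        with pytest.raises(ValueError, match="empty"):
            pairwise_agreement(a, ref)

    def test_window_mode(self):
        grid = grid_for({"c1": 3000}, 1000)
        a = make_set([Interval("c1", 0, 100), Interval("c1", 1200, 1300)], source="a")
        ref = make_set([Interval("c1", 50, 80)], source="r")
        assert pairwise_agreement(a, ref, mode="window", grid=grid) == 0.5


class TestCoverageSummary:
    def test_fraction_and_dedup(self, small_index):
        # small_index genome = 15 kb
        a = make_set(
            [Interval("chr1", 0, 1200), Interval("chr1", 0, 1200), Interval("chr2", 0, 600)],
            source="a",
            index=small_index,
        )
        df = coverage_summary([a])
        assert df.loc[0, "masked_bp"] == 1800
        assert df.loc[0, "genome_fraction"] == pytest.approx(1800 / 15_000)

    def test_planted_density_recovered(self):
        suite = simulate_annotation_suite(SimConfig(seed=3))
        df = coverage_summary([suite.true_set])
        assert df.loc[0, "genome_fraction"] == pytest.approx(
            suite.registry["planted_total_density"], abs=0.01
        )
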