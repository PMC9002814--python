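"""Heuristics: distance semantics, TAD lookup, nearest-gene search, dispatch."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tadassign import (
    ALL_HEURISTICS,
    GeneSet,
    GenomicRegion,
    Heuristic,
    TADSet,
    ValidationError,
    assign,
    assign_batch,
    genes_in_tad,
    locate_tad,
    nearest_gene,
    region_distance,
)

from conftest import brute_force_nearest, mk_gene, random_instance


class TestRegionDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((100, 200), (300, 320), 100),   # inner gap
            ((100, 200), (150, 400), 0),     # overlap
            ((200, 300), (100, 200), 0),     # abutting half-open intervals
            ((100, 200), (100, 200), 0),     # identical
        ],
    )
    def test_examples(self, a, b, expected):
        ra, rb = GenomicRegion("1", *a), GenomicRegion("1", *b)
        assert region_distance(ra, rb) == expected
        assert region_distance(rb, ra) == expected

    def test_cross_chromosome_rejected(self):
        with pytest.raises(ValidationError, match="chromosome"):
            region_distance(GenomicRegion("1", 0, 10), GenomicRegion("2", 0, 10))

    @given(
        s1=st.integers(0, 10**6), l1=st.integers(1, 10**5),
        s2=st.integers(0, 10**6), l2=st.integers(1, 10**5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetric_and_zero_iff_touching(self, s1, l1, s2, l2):
        a = GenomicRegion("1", s1, s1 + l1)
        b = GenomicRegion("1", s2, s2 + l2)
        d = region_distance(a, b)
        assert d == region_distance(b, a) >= 0
        touching = a.overlaps(b) or a.end == b.start or b.end == a.start
        assert (d == 0) == touching


class TestLocateTad:
    def test_midpoint_rule(self, two_tads):
        assert locate_tad(GenomicRegion("1", 600_000, 610_000), two_tads) == 1

    def test_boundary_spanning_region_goes_by_midpoint(self, two_tads):
        # midpoint 500000 falls in the second half-open TAD [500k, 1.2M)
        assert locate_tad(GenomicRegion("1", 490_000, 510_000), two_tads) == 1

    def test_chromosome_without_tads_gives_none(self, two_tads):
        assert locate_tad(GenomicRegion("2", 0, 100), two_tads) is None

    def test_outside_all_tads_gives_none(self, two_tads):
        assert locate_tad(GenomicRegion("1", 2_000_000, 2_000_100), two_tads) is None


class TestGenesInTad:
    def test_boundary_straddling_gene_belongs_by_tss(self, two_tads):
        # body straddles the 500k boundary; TSS 490k is in TAD 0 only
        genes = GeneSet([mk_gene("S", "1", 490_000, 520_000, "+")])
        assert genes_in_tad(0, genes, two_tads) == ["S"]
        assert genes_in_tad(1, genes, two_tads) == []

    def test_empty_tad(self, two_tads, two_gene_set):
        assert genes_in_tad(1, two_gene_set, two_tads) == []

    def test_sorted_by_tss(self, two_tads):
        genes = GeneSet([mk_gene("X", "1", 3000, 4000), mk_gene("Y", "1", 1000, 2000),
                         mk_gene("Z", "1", 5000, 6000)])
        assert genes_in_tad(0, genes, two_tads) == ["Y", "X", "Z"]


class TestNearestGene:
    def test_nearer_gene_wins(self, two_gene_set):
        a = nearest_gene(GenomicRegion("1", 300, 320), two_gene_set)
        assert (a.gene_id, a.distance) == ("A", 100)

    def test_equidistant_tie_broken_by_tss_distance(self, two_gene_set):
        # gaps to A and B are both 140; midpoint 350 is closer to B's TSS 500
        a = nearest_gene(GenomicRegion("1", 340, 360), two_gene_set)
        assert (a.gene_id, a.distance) == ("B", 140)

    def test_full_tie_broken_by_gene_id(self):
        genes = GeneSet([mk_gene("zz", "1", 100, 200), mk_gene("aa", "1", 100, 200)])
        a = nearest_gene(GenomicRegion("1", 300, 320), genes)
        assert a.gene_id == "aa"

    def test_overlap_gives_distance_zero(self, two_gene_set):
        a = nearest_gene(GenomicRegion("1", 150, 160), two_gene_set)
        assert (a.gene_id, a.distance) == ("A", 0)

    def test_filter_excluding_all_gives_none(self, two_gene_set):
        a = nearest_gene(GenomicRegion("1", 300, 320), two_gene_set,
                         candidate_filter=lambda g: False)
        assert a.gene_id is None and a.distance is None

    def test_unknown_chromosome_gives_none(self, two_gene_set):
        a = nearest_gene(GenomicRegion("9", 300, 320), two_gene_set)
        assert a.gene_id is None

    def test_tss_distance_mode(self):
        # region overlaps X's body but is nearer Y's TSS
        genes = GeneSet([mk_gene("X", "1", 100, 10_000, "+"),
                         mk_gene("Y", "1", 5_200, 9_000, "+")])
        body = nearest_gene(GenomicRegion("1", 5_000, 5_100), genes, distance_mode="body")
        tss = nearest_gene(GenomicRegion("1", 5_000, 5_100), genes, distance_mode="tss")
        assert body.gene_id == "X" and body.distance == 0
        assert tss.gene_id == "Y" and tss.distance == 100

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(20240917)
        for _ in range(30):
            genes, regions = random_instance(rng, max_genes=120, max_regions=60)
            gs = GeneSet(genes)
            expressed = {g.gene_id for g in genes if rng.random() < 0.5}
            for flt in (None, lambda g: g.gene_id in expressed):
                for r in regions:
                    got = nearest_gene(r, gs, candidate_filter=flt)
                    want_id, want_d = brute_force_nearest(r, genes, flt)
                    assert (got.gene_id, got.distance) == (want_id, want_d)


class TestAssign:
    @pytest.fixture
    def landscape(self, two_gene_set, two_tads):
        return two_gene_set, two_tads

    def test_all_expressed_makes_ne_equal_n(self, landscape):
        genes, tads = landscape
        r = GenomicRegion("1", 300, 320)
        n = assign(r, genes, tads, None, Heuristic.N)
        ne = assign(r, genes, tads, {"A", "B"}, Heuristic.NE)
        assert (n.gene_id, n.distance) == (ne.gene_id, ne.distance)

    def test_single_covering_tad_makes_ntad_equal_n(self, two_gene_set):
        tads = TADSet([GenomicRegion("1", 0, 10_000_000)])
        r = GenomicRegion("1", 300, 320)
        n = assign(r, two_gene_set, tads, None, Heuristic.N)
        nt = assign(r, two_gene_set, tads, None, Heuristic.N_TAD)
        assert (n.gene_id, n.distance) == (nt.gene_id, nt.distance)

    def test_unexpressed_only_tad_gene_splits_ne_tad_from_n_tad(self):
        genes = GeneSet([mk_gene("U", "1", 1000, 2000)])
        tads = TADSet([GenomicRegion("1", 0, 100_000)])
        r = GenomicRegion("1", 5_000, 5_100)
        assert assign(r, genes, tads, set(), Heuristic.N_TAD).gene_id == "U"
        assert assign(r, genes, tads, set(), Heuristic.NE_TAD).gene_id is None

    def test_region_outside_tads_gives_none_for_tad_heuristics(self, landscape):
        genes, tads = landscape
        r = GenomicRegion("1", 5_000_000, 5_000_100)
        a = assign(r, genes, tads, None, Heuristic.N_TAD)
        assert a.gene_id is None and a.tad_id is None

    def test_tad_assignment_gene_tss_inside_reported_tad(self, landscape):
        genes, tads = landscape
        a = assign(GenomicRegion("1", 300, 320), genes, tads, None, Heuristic.N_TAD)
        assert a.tad_id == 0
        assert tads.region(a.tad_id).contains_point(genes.get(a.gene_id).tss)

    def test_unknown_heuristic_rejected(self, landscape):
        genes, tads = landscape
        with pytest.raises(ValueError):
            assign(GenomicRegion("1", 300, 320), genes, tads, None, "NEAREST")

    def test_restriction_monotonicity(self):
        rng = np.random.default_rng(7)
        genes, regions = random_instance(rng, max_genes=150, max_regions=80)
        gs = GeneSet(genes)
        tads = TADSet([GenomicRegion("1", s, s + 1_000_000) for s in range(0, 10_000_000, 1_000_000)])
        for r in regions:
            n = assign(r, gs, tads, None, Heuristic.N)
            nt = assign(r, gs, tads, None, Heuristic.N_TAD)
            if n.gene_id is not None and nt.gene_id is not None:
                assert nt.distance >= n.distance

    def test_shrinking_expressed_set_never_creates_assignments(self):
        rng = np.random.default_rng(11)
        genes, regions = random_instance(rng, max_genes=100, max_regions=50)
        gs = GeneSet(genes)
        ids = sorted(g.gene_id for g in genes)
        big = set(ids)
        small = set(ids[: len(ids) // 3])
        for r in regions:
            a_big = assign(r, gs, None, big, Heuristic.NE)
            a_small = assign(r, gs, None, small, Heuristic.NE)
            if a_big.gene_id is None:
                assert a_small.gene_id is None

    def test_assign_is_pure(self, landscape):
        genes, tads = landscape
        r = GenomicRegion("1", 340, 360)
        first = assign(r, genes, tads, {"A"}, Heuristic.NE_TAD)
        for _ in range(3):
            again = assign(r, genes, tads, {"A"}, Heuristic.NE_TAD)
            assert again == first


class TestAssignBatch:
    def test_regions_times_heuristics_rows(self, two_gene_set, two_tads):
        regions = [GenomicRegion("1", i * 1000, i * 1000 + 100) for i in range(10)]
        t = assign_batch(regions, two_gene_set, two_tads, {"A"}, ALL_HEURISTICS)
        assert len(t) == 40

    def test_empty_region_list(self, two_gene_set, two_tads):
        t = assign_batch([], two_gene_set, two_tads, {"A"}, ALL_HEURISTICS)
        assert t.empty

    def test_invariant_to_input_order(self, two_gene_set, two_tads):
        regions = [GenomicRegion("1", i * 1000, i * 1000 + 100) for i in range(8)]
        fwd = assign_batch(regions, two_gene_set, two_tads, {"A"}, ALL_HEURISTICS)
        rev = assign_batch(regions[::-1], two_gene_set, two_tads, {"A"}, ALL_HEURISTICS)
        assert fwd.equals(rev)

    def test_unknown_chromosome_yields_none_rows(self, two_gene_set, two_tads):
        t = assign_batch([GenomicRegion("7", 0, 100)], two_gene_set, two_tads,
                         {"A"}, [Heuristic.N])
        assert pd.isna(t.loc[0, "gene_id"]) and pd.isna(t.loc[0, "distance"])
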