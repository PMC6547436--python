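"""Boundary windows, observed/expected counts, genome aggregation, filters."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xdc import boundary_stats as bs
from xdc.models import AlignmentCounts, DomainAssignment, ProteinRecord


def brute_force_windows(intervals, length):
    out = set()
    for s, e in intervals:
        for edge in (s, e):
            out |= {edge - 1, edge, edge + 1}
    return {r for r in out if 1 <= r <= length}


class TestConsensusCall:
    def test_six_of_eight_is_disordered(self):
        tracks = [[1] * 10 for _ in range(6)] + [[0] * 10 for _ in range(2)]
        assert bs.consensus_call(tracks).tolist() == [1] * 10

    def test_five_of_eight_is_ordered(self):
        tracks = [[1] * 10 for _ in range(5)] + [[0] * 10 for _ in range(3)]
        assert bs.consensus_call(tracks).tolist() == [0] * 10

    def test_single_track_identity(self):
        track = [0, 1, 1, 0, 1]
        for threshold in (0.5, 0.75, 1.0):
            assert bs.consensus_call([track], threshold).tolist() == track

    def test_ragged_tracks_error(self):
        with pytest.raises(ValueError, match="ragged"):
            bs.consensus_call([[1, 0], [1, 0, 1]])

    def test_no_tracks_error(self):
        with pytest.raises(ValueError):
            bs.consensus_call([])


class TestBoundaryWindows:
    def test_interior_domain_six_residues(self):
        assert bs.build_boundary_windows([(10, 50)], 100) == {9, 10, 11, 49, 50, 51}

    def test_edge_clipping(self):
        assert bs.build_boundary_windows([(1, 100)], 100) == {1, 2, 99, 100}

    def test_adjacent_domains_union_not_sum(self):
        got = bs.build_boundary_windows([(10, 20), (21, 30)], 100)
        assert got == {9, 10, 11, 19, 20, 21, 22, 29, 30, 31}
        assert len(got) == 10

    def test_out_of_range_interval(self):
        with pytest.raises(ValueError):
            bs.build_boundary_windows([(0, 5)], 100)
        with pytest.raises(ValueError):
            bs.build_boundary_windows([(90, 120)], 100)

    @given(
        st.integers(min_value=5, max_value=80).flatmap(
            lambda L: st.tuples(
                st.just(L),
                st.lists(
                    st.tuples(
                        st.integers(min_value=1, max_value=L),
                        st.integers(min_value=1, max_value=L),
                    ).map(lambda t: (min(t), max(t))),
                    min_size=1,
                    max_size=5,
                ),
            )
        )
    )
    @settings(max_examples=150, derandomize=True)
    def test_matches_brute_force_and_size_bound(self, case):
        L, intervals = case
        got = bs.build_boundary_windows(intervals, L)
        assert got == brute_force_windows(intervals, L)
        assert len(got) <= 6 * len(intervals)


class TestCounts:
    def test_disjoint(self):
        assert bs.count_observed([33, 67], {9, 10, 11, 49, 50, 51}) == 0

    def test_both_inside(self):
        assert bs.count_observed([10, 50], {9, 10, 11, 49, 50, 51}) == 2

    def test_multiset_counting(self):
        assert bs.count_observed([11, 11], {10, 11, 12}) == 2

    def test_expected_examples(self):
        assert bs.expected_aligned(3, 6, 100) == pytest.approx(0.18)
        assert bs.expected_aligned(0, 6, 100) == 0
        assert bs.expected_aligned(5, 100, 100) == 5

    def test_expected_validation(self):
        with pytest.raises(ValueError):
            bs.expected_aligned(1, 6, 0)
        with pytest.raises(ValueError):
            bs.expected_aligned(1, 101, 100)

    @pytest.mark.parametrize(
        "L, k, intervals",
        [(12, 2, [(4, 8)]), (20, 3, [(5, 9), (14, 18)]), (30, 3, [(2, 25)])],
    )
    def test_expected_equals_exhaustive_enumeration(self, L, k, intervals):
        """Oracle: average the observed count over every placement of k
        junctions (with replacement) on residues 1..L."""
        windows = bs.build_boundary_windows(intervals, L)
        total = 0
        for placement in itertools.product(range(1, L + 1), repeat=k):
            total += bs.count_observed(placement, windows)
        exact_mean = total / L**k
        assert bs.expected_aligned(k, len(windows), L) == pytest.approx(
            exact_mean, abs=1e-9
        )


class TestGenomeAggregate:
    @staticmethod
    def _pc(observed, expected, n_b=2, n_w=6, n_r=100):
        return AlignmentCounts("protein", "domain", observed, expected, n_b,
                               n_w, n_r)

    def test_additivity(self):
        agg = bs.genome_aggregate([self._pc(1, 0.5), self._pc(0, 0.5)], "domain")
        assert (agg.observed, agg.expected) == (1, 1.0)
        assert agg.ratio == pytest.approx(1.0)
        assert agg.n_proteins == 2

    def test_empty_set_flagged_undefined(self, caplog):
        agg = bs.genome_aggregate([], "domain")
        assert math.isnan(agg.ratio)
        assert "undefined" in caplog.text

    def test_ratio_scale_invariance(self):
        agg = bs.genome_aggregate([self._pc(2, 1.0)] * 10, "domain")
        assert agg.ratio == pytest.approx(2.0)


def _record(pid, gid, n_exons, with_domain=True, length=100):
    domains = [DomainAssignment(pid, "d1", 10, 50)] if with_domain else []
    return ProteinRecord(
        protein_id=pid, genome_id=gid, length=length,
        junction_residues=list(range(2, n_exons + 1)), n_cds_exons=n_exons,
        domains=domains, architecture="d1" if with_domain else "",
    )


class TestApplyFilters:
    def test_single_exon_proteins_removed(self):
        recs = [_record("a", "G", 1), _record("b", "G", 3)]
        eligible, _ = bs.apply_filters(recs, min_multiexon_proteins=1)
        assert [r.protein_id for r in eligible["G"]] == ["b"]

    def test_sparse_genome_excluded(self):
        recs = [_record(f"p{i}", "G", 2) for i in range(5)]
        eligible, report = bs.apply_filters(recs, min_multiexon_proteins=200)
        assert eligible == {}
        assert report[0]["excluded"] and "200" in report[0]["reason"]

    def test_threshold_zero_disables_exclusion(self):
        recs = [_record("p", "G", 2, with_domain=False)]
        eligible, report = bs.apply_filters(recs, min_multiexon_proteins=0)
        assert "G" in eligible and not report[0]["excluded"]
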