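"""Segment extraction, weighting schemes, and anchor-file writers."""

import random
from itertools import combinations

import pytest

from ms4anchors.anchors import (
    AnchorSegment,
    extract_segments,
    weight_segments,
    write_ballast,
    write_dialign_anchors,
    write_tcoffee_lib,
)
from ms4anchors.errors import ParameterError
from ms4anchors.ms4 import columns_from_site_maps
from ms4anchors.sitespace import SequenceSet
from oracles import random_column_set


def cols_of(*maps):
    return columns_from_site_maps(list(maps))


class TestExtractSegments:
    def test_consecutive_pairs_merge(self):
        segs = extract_segments(cols_of({0: 0, 1: 0}, {0: 1, 1: 1}))
        assert segs == [AnchorSegment(0, 1, 0, 0, 2)]

    def test_gap_breaks_run(self):
        segs = extract_segments(cols_of({0: 0, 1: 0}, {0: 2, 1: 2}))
        assert segs == [AnchorSegment(0, 1, 0, 0, 1), AnchorSegment(0, 1, 2, 2, 1)]

    def test_wide_column_expands_pairwise(self):
        segs = extract_segments(cols_of({0: 3, 1: 5, 2: 7}))
        assert segs == [
            AnchorSegment(0, 1, 3, 5, 1),
            AnchorSegment(0, 2, 3, 7, 1),
            AnchorSegment(1, 2, 5, 7, 1),
        ]

    def test_run_may_cross_columns_of_different_span(self):
        # offsets 0,1 supported for the (0,1) pair by columns of different width
        segs = extract_segments(cols_of({0: 0, 1: 0, 2: 4}, {0: 1, 1: 1}))
        pairs_01 = [s for s in segs if (s.seq_a, s.seq_b) == (0, 1)]
        assert pairs_01 == [AnchorSegment(0, 1, 0, 0, 2)]

    @pytest.mark.parametrize("seed", range(20))
    def test_round_trip_and_maximality(self, seed):
        rng = random.Random(seed)
        cols, _ = random_column_set(rng, max_cols=8)
        segs = extract_segments(cols)
        # conservation: covered site pairs == within-column pairs, per sequence pair
        covered = {
            (s.seq_a, s.seq_b, s.start_a + t, s.start_b + t)
            for s in segs
            for t in range(s.length)
        }
        expected = {
            (sa, sb, pa, pb)
            for col in cols
            for (sa, pa), (sb, pb) in combinations(col.sites, 2)
        }
        assert covered == expected
        assert len(covered) == sum(s.length for s in segs)  # no double cover
        # maximality: no two segments of one pair are diagonal-adjacent
        by_pair = {}
        for s in segs:
            by_pair.setdefault((s.seq_a, s.seq_b), []).append(s)
        for group in by_pair.values():
            for s1, s2 in combinations(group, 2):
                assert not (
                    s1.start_a + s1.length == s2.start_a
                    and s1.start_b + s1.length == s2.start_b
                )
                assert not (
                    s2.start_a + s2.length == s1.start_a
                    and s2.start_b + s2.length == s1.start_b
                )


class TestWeighting:
    def test_length10_is_ten_times_length(self):
        segs = [AnchorSegment(0, 1, 0, 0, 2), AnchorSegment(0, 1, 4, 4, 1)]
        weighted = weight_segments(segs, "length10")
        assert [s.weight for s in weighted] == [20, 10]

    def test_tcoffee_uniform_is_hundred_m(self):
        segs = [AnchorSegment(0, 1, 0, 0, 2), AnchorSegment(1, 2, 0, 0, 7)]
        weighted = weight_segments(segs, "tcoffee_uniform", n_seqs=5)
        assert [s.weight for s in weighted] == [500, 500]

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ParameterError):
            weight_segments([], "quadratic")

    def test_uniform_scheme_needs_sequence_count(self):
        with pytest.raises(ParameterError):
            weight_segments([AnchorSegment(0, 1, 0, 0, 1)], "tcoffee_uniform")


@pytest.fixture
def small_case():
    seqs = SequenceSet.from_strings(["ACGTA", "ACGT"], ids=["alpha", "beta"])
    cols = cols_of({0: 0, 1: 0}, {0: 1, 1: 1}, {0: 3, 1: 3})
    segs = weight_segments(extract_segments(cols), "length10")
    return seqs, segs


class TestWriters:
    def test_dialign_golden(self, tmp_path, small_case):
        seqs, segs = small_case
        out = tmp_path / "anchors.txt"
        write_dialign_anchors(segs, seqs, out)
        assert out.read_text() == "1 2 1 1 2 20\n1 2 4 4 1 10\n"

    def test_dialign_empty(self, tmp_path, small_case):
        seqs, _ = small_case
        out = tmp_path / "empty.txt"
        write_dialign_anchors([], seqs, out)
        assert out.read_text() == ""

    def test_ballast_golden(self, tmp_path, small_case):
        seqs, segs = small_case
        out = tmp_path / "anchors.ballast"
        write_ballast(segs, seqs, out)
        assert out.read_text() == (
            "# BALLAST anchor list\n"
            "# query: alpha\n"
            "alpha beta 1 1 2 20\n"
            "alpha beta 4 4 1 10\n"
        )

    def test_tcoffee_golden(self, tmp_path, small_case):
        seqs, segs = small_case
        segs = weight_segments(segs, "tcoffee_uniform", n_seqs=seqs.n)
        out = tmp_path / "lib.tc"
        write_tcoffee_lib(segs, seqs, out)
        assert out.read_text() == (
            "! TC_LIB_FORMAT_01\n"
            "2\n"
            "alpha 5 ACGTA\n"
            "beta 4 ACGT\n"
            "#1 2\n"
            "1 1 200\n"
            "2 2 200\n"
            "4 4 200\n"
            "! SEQ_1_TO_N\n"
        )

    def test_tcoffee_empty_set_keeps_frame(self, tmp_path, small_case):
        seqs, _ = small_case
        out = tmp_path / "lib.tc"
        write_tcoffee_lib([], seqs, out)
        assert out.read_text() == (
            "! TC_LIB_FORMAT_01\n2\nalpha 5 ACGTA\nbeta 4 ACGT\n! SEQ_1_TO_N\n"
        )

    def test_unweighted_segments_rejected(self, tmp_path, small_case):
        seqs, _ = small_case
        with pytest.raises(ParameterError):
            write_dialign_anchors([AnchorSegment(0, 1, 0, 0, 1)], seqs, tmp_path / "x")

    def test_writers_deterministic(self, tmp_path, small_case):
        seqs, segs = small_case
        a, b = tmp_path / "a", tmp_path / "b"
        for writer in (write_dialign_anchors, write_ballast):
            writer(segs, seqs, a)
            writer(segs, seqs, b)
            assert a.read_bytes() == b.read_bytes()
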