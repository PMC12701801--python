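"""Interval index: overlap queries, counts, nearest, pruning behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

from rangeframe import CoordSystem, IntervalFrame, QueryStats, build_index

from conftest import oracle_nearest, oracle_overlap_pairs, random_instance


def make_frame(rows):
    return IntervalFrame(pd.DataFrame(rows, columns=["contig", "start", "end"]))


class TestBuild:
    def test_empty_frame_answers_no_hits(self):
        idx = build_index(make_frame([]))
        assert idx.n_items == 0
        assert idx.query_overlaps(("chr1", 0, 100)) == []
        assert idx.count_overlaps(("chr1", 0, 100)) == 0
        assert idx.nearest(("chr1", 0, 100)) == []

    def test_cardinality(self):
        idx = build_index(make_frame([("chr1", 0, 10), ("chr1", 5, 20), ("chr2", 0, 3)]))
        assert idx.n_items == 3

    def test_every_interval_finds_itself(self):
        f = make_frame([("chr1", 0, 10), ("chr1", 5, 20), ("chr2", 0, 3), ("chr1", 7, 7)])
        idx = build_index(f)
        for iv in f.intervals():
            assert iv.row_id in idx.query_overlaps(iv)

    def test_one_based_build_side_is_normalized(self):
        f = IntervalFrame(
            pd.DataFrame({"contig": ["chr1"], "start": [1], "end": [10]}),
            CoordSystem.ONE_BASED_CLOSED,
        )
        idx = build_index(f)
        assert idx.query_overlaps(("chr1", 0, 1)) == [0]  # covers base 0 half-open


class TestQueryOverlaps:
    def test_spanning_query_hits_both(self):
        idx = build_index(make_frame([("chr1", 0, 10), ("chr1", 15, 20)]))
        assert sorted(idx.query_overlaps(("chr1", 5, 16))) == [0, 1]

    def test_unknown_contig_is_empty(self):
        idx = build_index(make_frame([("chr1", 0, 10)]))
        assert idx.query_overlaps(("chr2", 0, 100)) == []

    def test_touching_endpoints_do_not_overlap(self):
        idx = build_index(make_frame([("chr1", 0, 10), ("chr1", 15, 20)]))
        assert idx.query_overlaps(("chr1", 10, 15)) == []

    def test_zero_length_query_behaves_as_point(self):
        idx = build_index(make_frame([("chr1", 5, 10)]))
        assert idx.query_overlaps(("chr1", 5, 5)) == [0]
        assert idx.query_overlaps(("chr1", 9, 9)) == [0]
        assert idx.query_overlaps(("chr1", 10, 10)) == []

    def test_zero_length_build_interval_behaves_as_point(self):
        idx = build_index(make_frame([("chr1", 7, 7)]))
        assert idx.query_overlaps(("chr1", 0, 10)) == [0]
        assert idx.query_overlaps(("chr1", 7, 9)) == [0]
        assert idx.query_overlaps(("chr1", 0, 7)) == []


class TestCountOverlaps:
    def test_count_equals_query_length(self):
        idx = build_index(make_frame([("chr1", 0, 10), ("chr1", 15, 20)]))
        assert idx.count_overlaps(("chr1", 5, 16)) == 2

    def test_stacked_duplicates_counted_per_row(self):
        idx = build_index(make_frame([("chr1", 0, 10)] * 5))
        assert idx.count_overlaps(("chr1", 3, 4)) == 5


class TestNearest:
    def test_closer_right_neighbour_wins(self):
        idx = build_index(make_frame([("chr1", 0, 9), ("chr1", 119, 130)]))
        assert idx.nearest(("chr1", 99, 110)) == [(1, 9)]

    def test_overlap_gives_distance_zero(self):
        idx = build_index(make_frame([("chr1", 0, 9)]))
        assert idx.nearest(("chr1", 5, 20)) == [(0, 0)]

    def test_touching_gives_distance_zero_but_no_overlap(self):
        idx = build_index(make_frame([("chr1", 10, 20)]))
        assert idx.query_overlaps(("chr1", 0, 10)) == []
        assert idx.nearest(("chr1", 0, 10)) == [(0, 0)]

    def test_equidistant_tie_breaks_by_smaller_start(self):
        idx = build_index(make_frame([("chr1", 130, 140), ("chr1", 0, 10)]))
        # query [60, 70): left gap 50, right gap 60 -> left; then equidistant:
        idx2 = build_index(make_frame([("chr1", 120, 130), ("chr1", 0, 20)]))
        # query [70, 70+30): gaps 70-20=50 and 120-100=20 -> right
        assert idx.nearest(("chr1", 60, 70)) == [(1, 50)]
        assert idx2.nearest(("chr1", 70, 100)) == [(0, 20)]
        # true tie: [50, 60) between [0,10) (gap 40) and [100,110) (gap 40)
        idx3 = build_index(make_frame([("chr1", 100, 110), ("chr1", 0, 10)]))
        assert idx3.nearest(("chr1", 50, 60)) == [(1, 40)]

    def test_k_returns_distinct_rows_with_nondecreasing_distances(self):
        idx = build_index(
            make_frame([("chr1", 0, 10), ("chr1", 30, 40), ("chr1", 100, 105)])
        )
        got = idx.nearest(("chr1", 12, 20), k=3)
        # gaps: [0,10) -> 2, [30,40) -> 10, [100,105) -> 80
        assert got == [(0, 2), (1, 10), (2, 80)]
        assert len({rid for rid, _ in got}) == 3

    def test_k_capped_at_contig_population(self):
        idx = build_index(make_frame([("chr1", 0, 10)]))
        assert len(idx.nearest(("chr1", 50, 60), k=5)) == 1


@pytest.mark.parametrize("seed", range(40))
def test_query_matches_nested_loop_oracle(seed):
    a, b = random_instance(seed, max_n=200)
    idx = build_index(b)
    qi, bj = oracle_overlap_pairs(a, b)
    expected = {}
    for q, j in zip(qi, bj):
        expected.setdefault(int(q), []).append(int(j))
    for iv in a.intervals():
        got = sorted(idx.query_overlaps(iv))
        assert got == sorted(expected.get(iv.row_id, []))
        assert idx.count_overlaps(iv) == len(got)


@pytest.mark.parametrize("seed", range(20))
def test_nearest_matches_brute_force(seed):
    a, b = random_instance(seed, max_n=150)
    idx = build_index(b)
    for k in (1, 3):
        expected = oracle_nearest(a, b, k=k)
        for iv in a.intervals():
            got = idx.nearest(iv, k=k)
            assert got == expected[iv.row_id]
            if got:
                ds = [d for _, d in got]
                assert ds == sorted(ds)
                # distance 0 iff overlap or touch
                overlaps = idx.query_overlaps(iv)
                touches = any(
                    biv.end == iv.start or biv.start == iv.end
                    for biv in b.intervals()
                    if biv.contig == iv.contig
                )
                assert (ds[0] == 0) == (bool(overlaps) or touches)


def test_repeated_queries_are_identical():
    _, b = random_instance(3)
    idx = build_index(b)
    q = ("chr1", 100, 5000)
    first = idx.query_overlaps(q)
    for _ in range(5):
        assert idx.query_overlaps(q) == first
        assert idx.nearest(q, k=2) == idx.nearest(q, k=2)


def test_sparse_queries_inspect_logarithmic_candidates():
    # n disjoint unit-spaced intervals; each query overlaps exactly one
    n = 4096
    rows = [("chr1", 10 * i, 10 * i + 5) for i in range(n)]
    idx = build_index(make_frame(rows))
    bound = 2 * (math.log2(n) + 1 + 8)
    for i in range(0, n, 97):
        stats = QueryStats()
        hits = idx.query_overlaps(("chr1", 10 * i + 1, 10 * i + 4), stats=stats)
        assert hits == [i]
        assert stats.inspected <= bound


def test_long_interval_mixture_triggers_decomposition_and_stays_correct():
    rng = np.random.default_rng(0)
    n = 2000
    s = rng.integers(0, 100_000, n).astype(np.int64)
    # 20% very long intervals covering most of the contig
    ln = np.where(rng.random(n) < 0.2, rng.integers(50_000, 90_000, n), rng.integers(1, 50, n))
    f = IntervalFrame(pd.DataFrame({"contig": "chr1", "start": s, "end": s + ln}))
    idx = build_index(f)
    cl = idx.contig_arrays("chr1")
    assert len(cl.comp_bounds) > 2  # decomposed into multiple sublists
    a = IntervalFrame(
        pd.DataFrame(
            {"contig": "chr1", "start": np.arange(0, 100_000, 1013), "end": np.arange(0, 100_000, 1013) + 500}
        )
    )
    qi, bj = oracle_overlap_pairs(a, f)
    expected = {}
    for q, j in zip(qi, bj):
        expected.setdefault(int(q), []).append(int(j))
    for iv in a.intervals():
        assert sorted(idx.query_overlaps(iv)) == sorted(expected.get(iv.row_id, []))
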