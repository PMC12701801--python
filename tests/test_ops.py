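"""Table-level operations: joins, counts, coverage, and their invariants."""

import numpy as np
import pandas as pd
import pytest

from rangeframe import (
    BuildEngine,
    CoordSystem,
    IntervalFrame,
    ValidationError,
    convert_coordinates,
    count_overlaps,
    coverage,
    nearest,
    overlap,
)

from conftest import (
    assert_same_rows,
    oracle_counts,
    oracle_coverage,
    oracle_nearest,
    oracle_overlap_pairs,
    random_instance,
    row_multiset,
)


def hf(rows, cols=("contig", "start", "end"), extra=None):
    df = pd.DataFrame(rows, columns=list(cols))
    if extra:
        for k, v in extra.items():
            df[k] = v
    return IntervalFrame(df)


class TestOverlap:
    def test_single_pair(self):
        a = hf([("chr1", 149, 250)])
        b = hf([("chr1", 99, 200), ("chr1", 299, 400)])
        r = overlap(a, b)
        assert r.n_rows == 1
        assert r.data.loc[0, "start_1"] == 149 and r.data.loc[0, "start_2"] == 99

    def test_empty_build_side(self):
        a = hf([("chr1", 0, 10), ("chr1", 20, 30)])
        b = hf([])
        assert overlap(a, b, how="inner").n_rows == 0
        left = overlap(a, b, how="left")
        assert left.n_rows == 2
        assert left.data["start_2"].isna().all()

    def test_self_join_on_disjoint_set(self):
        a = hf([("chr1", 0, 10), ("chr1", 20, 30), ("chr2", 5, 9)])
        r = overlap(a, a)
        assert r.n_rows == 3
        assert (r.data["start_1"] == r.data["start_2"]).all()

    def test_left_join_keeps_unmatched_probe_rows(self):
        a = hf([("chr1", 0, 10), ("chr3", 0, 10)])
        b = hf([("chr1", 5, 9)])
        r = overlap(a, b, how="left")
        assert r.n_rows == 2
        assert r.data["contig_2"].isna().tolist() == [False, True]

    def test_custom_suffixes(self):
        a = hf([("chr1", 0, 10)])
        b = hf([("chr1", 5, 9)])
        r = overlap(a, b, suffixes=("_query", "_target"))
        assert "start_query" in r.data.columns and "start_target" in r.data.columns

    def test_invalid_frame_reports_violations(self):
        bad = hf([("chr1", 10, 5)])
        good = hf([("chr1", 0, 10)])
        with pytest.raises(ValidationError) as exc:
            overlap(bad, good)
        assert exc.value.violations[0].row_id == 0

    def test_how_validated(self):
        a = hf([("chr1", 0, 10)])
        with pytest.raises(ValueError):
            overlap(a, a, how="outer")


class TestNearest:
    def test_worked_example(self):
        a = hf([("chr1", 99, 110)])
        b = hf([("chr1", 0, 9), ("chr1", 119, 130)])
        r = nearest(a, b)
        assert r.data["distance"].tolist() == [9]
        assert r.data.loc[0, "start_2"] == 119

    def test_contig_absent_from_build_yields_null_row(self):
        a = hf([("chrM", 0, 10)])
        b = hf([("chr1", 0, 9)])
        r = nearest(a, b)
        assert r.n_rows == 1
        assert pd.isna(r.data.loc[0, "distance"]) and pd.isna(r.data.loc[0, "start_2"])

    def test_k_two_distances_nondecreasing(self):
        a = hf([("chr1", 50, 60)])
        b = hf([("chr1", 0, 10), ("chr1", 100, 110)])
        r = nearest(a, b, k=2)
        assert r.n_rows == 2
        d = r.data["distance"].tolist()
        assert d == sorted(d) == [40, 40]

    def test_every_probe_row_appears(self):
        a, b = random_instance(7)
        r = nearest(a, b, k=1)
        assert sorted(r.data["tag_1"].unique()) == sorted(a.data["tag"].unique())


class TestCountOverlaps:
    def test_basic_counts(self):
        a = hf([("chr1", 0, 100)])
        b = hf([("chr1", 10, 20), ("chr1", 50, 60), ("chr1", 200, 300)])
        r = count_overlaps(a, b)
        assert r.data["count"].tolist() == [2]

    def test_empty_build_gives_zeros_in_probe_order(self):
        a = hf([("chr1", 0, 10), ("chr2", 5, 6)])
        r = count_overlaps(a, hf([]))
        assert r.data["count"].tolist() == [0, 0]
        assert r.data["contig_1"].tolist() == ["chr1", "chr2"]

    @pytest.mark.parametrize("seed", range(20))
    def test_count_sum_equals_inner_join_size(self, seed):
        a, b = random_instance(seed, max_n=150)
        assert count_overlaps(a, b).data["count"].sum() == overlap(a, b).n_rows


class TestCoverage:
    def test_stacked_build_intervals_not_double_counted(self):
        a = hf([("chr1", 0, 10)])
        b = hf([("chr1", 2, 5), ("chr1", 4, 8)])
        r = coverage(a, b)
        assert r.data["covered"].tolist() == [6]
        assert r.data["coverage_fraction"].tolist() == [0.6]

    def test_empty_build_gives_zero(self):
        r = coverage(hf([("chr1", 0, 10)]), hf([]))
        assert r.data["covered"].tolist() == [0]
        assert r.data["coverage_fraction"].tolist() == [0.0]

    def test_full_cover_gives_fraction_one(self):
        a = hf([("chr1", 5, 15)])
        b = hf([("chr1", 5, 15)])
        r = coverage(a, b)
        assert r.data["covered"].tolist() == [10]
        assert r.data["coverage_fraction"].tolist() == [1.0]

    def test_zero_length_probe_fraction_is_zero(self):
        a = hf([("chr1", 5, 5)])
        b = hf([("chr1", 0, 10)])
        r = coverage(a, b)
        assert r.data["covered"].tolist() == [0]
        assert r.data["coverage_fraction"].tolist() == [0.0]


@pytest.mark.parametrize("seed", range(20))
def test_all_ops_match_oracles(seed):
    a, b = random_instance(seed, max_n=150)
    qi, bj = oracle_overlap_pairs(a, b)
    r = overlap(a, b)
    got = sorted(zip(r.data["tag_1"], r.data["tag_2"]))
    exp = sorted((a.data["tag"].iloc[q], b.data["tag"].iloc[j]) for q, j in zip(qi, bj))
    assert got == exp
    assert count_overlaps(a, b).data["count"].tolist() == oracle_counts(a, b).tolist()
    assert coverage(a, b).data["covered"].tolist() == oracle_coverage(a, b).tolist()
    exp_near = oracle_nearest(a, b, k=1)
    rn = nearest(a, b, k=1)
    for i, grp in rn.data.groupby(rn.data["tag_1"].str.slice(1).astype(int), sort=True):
        if exp_near[i]:
            assert grp["distance"].tolist() == [d for _, d in exp_near[i]]
            assert grp["tag_2"].tolist() == [b.data["tag"].iloc[j] for j, _ in exp_near[i]]
        else:
            assert grp["distance"].isna().all()


def test_row_order_invariance():
    a, b = random_instance(13, max_n=100)
    rng = np.random.default_rng(0)
    a2 = IntervalFrame(a.data.sample(frac=1, random_state=1), a.coord_system)
    b2 = IntervalFrame(b.data.sample(frac=1, random_state=2), b.coord_system)
    for op in (overlap, count_overlaps, coverage):
        r1 = op(a, b)
        r2 = op(a2, b2)
        cols = [c for c in r1.data.columns]
        assert row_multiset(r1.data[cols]) == row_multiset(r2.data[cols])


def test_coordinate_system_invariance():
    a, b = random_instance(21, max_n=120, zero_len=False)
    a1 = convert_coordinates(a, CoordSystem.ONE_BASED_CLOSED)
    b1 = convert_coordinates(b, CoordSystem.ONE_BASED_CLOSED)
    # mixed conventions on input; output follows the probe frame
    for a_in, b_in in [(a1, b1), (a, b1), (a1, b)]:
        r_ref = overlap(a, b)
        r = overlap(a_in, b_in)
        back = r.data.copy()
        if a_in.coord_system is CoordSystem.ONE_BASED_CLOSED:
            back["start_1"] -= 1
            back["start_2"] -= 1
        assert_same_rows(back, r_ref.data)
    n_ref = nearest(a, b).data["distance"]
    assert n_ref.tolist() == nearest(a1, b1).data["distance"].tolist()


def test_payload_passes_through_unchanged():
    a = hf([("chr1", 0, 10)], extra={"meta": ["x\ty"], "num": [3]})
    b = hf([("chr1", 5, 9)], extra={"obj": [{"k": 1}]})
    r = overlap(a, b)
    assert r.data.loc[0, "meta_1"] == "x\ty"
    assert r.data.loc[0, "num_1"] == 3
    assert r.data.loc[0, "obj_2"] == {"k": 1}


def test_build_engine_reuse_matches_direct_call():
    a, b = random_instance(5, max_n=100)
    eng = BuildEngine(b)
    pd.testing.assert_frame_equal(overlap(a, eng).data, overlap(a, b).data)
    pd.testing.assert_frame_equal(coverage(a, eng).data, coverage(a, b).data)
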