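"""Shared test helpers: random instances and independent brute-force oracles.

The oracles are deliberately naive — full pairwise predicate evaluation for
joins and counts, a per-base bitmap for coverage and union size — so they
share no code path with the indexed implementation they check.
"""

import numpy as np
import pandas as pd
import pytest

from rangeframe import CoordSystem, IntervalFrame

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "fixed",
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("fixed")
except ImportError:  # pragma: no cover
    pass

CONTIG_POOL = ["chr1", "chr2", "chrX"]


def random_frame(rng, n, max_coord=100_000, contigs=CONTIG_POOL, zero_len=True, tag="x"):
    c = rng.choice(contigs, n)
    s = rng.integers(0, max_coord, n)
    ln = rng.integers(1, 2001, n)
    if zero_len and n:
        ln[rng.random(n) < 0.05] = 0
    df = pd.DataFrame(
        {
            "contig": c,
            "start": s.astype(np.int64),
            "end": (s + ln).astype(np.int64),
            "tag": [f"{tag}{i}" for i in range(n)],
        }
    )
    return IntervalFrame(df, CoordSystem.ZERO_BASED_HALF_OPEN)


def random_instance(seed, max_n=500, max_coord=100_000, zero_len=True):
    """A (probe, build) pair of random half-open frames, 1-3 contigs."""
    rng = np.random.default_rng(seed)
    contigs = list(rng.choice(CONTIG_POOL, size=int(rng.integers(1, 4)), replace=False))
    na = int(rng.integers(1, max_n + 1))
    nb = int(rng.integers(1, max_n + 1))
    a = random_frame(rng, na, max_coord, contigs, zero_len, tag="a")
    b = random_frame(rng, nb, max_coord, contigs, zero_len, tag="b")
    # inject duplicate build rows so multiset semantics are exercised
    if nb >= 4:
        dup = b.data.iloc[list(rng.integers(0, nb, 3))]
        b = IntervalFrame(
            pd.concat([b.data, dup], ignore_index=True), b.coord_system, b.cols
        )
    return a, b


# ---------------------------------------------------------------------------
# oracles (definitional, no index)


def _eff_ends(s, e):
    # zero-length intervals behave as points: [p, p+1) in the overlap predicate
    return np.maximum(e, s + 1)


def oracle_overlap_pairs(a: IntervalFrame, b: IntervalFrame):
    """All (probe row, build row) index pairs with >= 1 shared base."""
    ac, as_, ae = a.contigs, a.starts.astype(np.int64), a.ends.astype(np.int64)
    bc, bs, be = b.contigs, b.starts.astype(np.int64), b.ends.astype(np.int64)
    if len(ac) == 0 or len(bc) == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    aeff = _eff_ends(as_, ae)
    beff = _eff_ends(bs, be)
    m = (
        (ac[:, None] == bc[None, :])
        & (bs[None, :] < aeff[:, None])
        & (as_[:, None] < beff[None, :])
    )
    qi, bj = np.nonzero(m)
    return qi.astype(np.int64), bj.astype(np.int64)


def oracle_counts(a: IntervalFrame, b: IntervalFrame):
    qi, _ = oracle_overlap_pairs(a, b)
    return np.bincount(qi, minlength=a.n_rows).astype(np.int64)


def oracle_coverage(a: IntervalFrame, b: IntervalFrame, max_coord=200_000):
    """Per-probe covered bases via an explicit per-base bitmap."""
    bitmaps = {}
    for iv in b.intervals():
        bm = bitmaps.setdefault(iv.contig, np.zeros(max_coord, dtype=bool))
        bm[iv.start : iv.end] = True
    out = np.zeros(a.n_rows, dtype=np.int64)
    for iv in a.intervals():
        bm = bitmaps.get(iv.contig)
        if bm is not None:
            out[iv.row_id] = int(bm[iv.start : iv.end].sum())
    return out


def oracle_union_size(frame: IntervalFrame, max_coord=200_000):
    """Total bases in the union of a half-open frame, via bitmap."""
    total = 0
    for contig in set(map(str, frame.contigs)):
        bm = np.zeros(max_coord, dtype=bool)
        for iv in frame.intervals():
            if iv.contig == contig:
                bm[iv.start : iv.end] = True
        total += int(bm.sum())
    return total


def oracle_distance(as_, ae, bs, be):
    return max(0, bs - ae, as_ - be)


def oracle_nearest(a: IntervalFrame, b: IntervalFrame, k=1):
    """Brute-force k-nearest with the documented tie-break, per probe row.

    Evaluates the full probe x build distance matrix, then sorts each probe's
    same-contig candidates by (distance, start, end, row).  Returns a list
    (one entry per probe row) of lists of (build row, distance).
    """
    ac, as_, ae = a.contigs, a.starts.astype(np.int64), a.ends.astype(np.int64)
    bc, bs, be = b.contigs, b.starts.astype(np.int64), b.ends.astype(np.int64)
    if b.n_rows == 0:
        return [[] for _ in range(a.n_rows)]
    same = ac[:, None] == bc[None, :]
    dist = np.maximum(0, np.maximum(bs[None, :] - ae[:, None], as_[:, None] - be[None, :]))
    jidx = np.arange(b.n_rows)
    out = []
    for i in range(a.n_rows):
        cand = np.flatnonzero(same[i])
        if cand.size == 0:
            out.append([])
            continue
        order = np.lexsort((cand, be[cand], bs[cand], dist[i, cand]))[:k]
        out.append([(int(cand[o]), int(dist[i, cand[o]])) for o in order])
    return out


# ---------------------------------------------------------------------------
# multiset comparison helpers


def row_multiset(df: pd.DataFrame):
    """Canonical sorted list of row tuples (nulls normalized) for multiset equality."""

    def norm(v):
        if v is None or v is pd.NA or (isinstance(v, float) and np.isnan(v)):
            return None
        if isinstance(v, (np.integer, int)):
            return int(v)
        if isinstance(v, (np.floating, float)):
            return float(v)
        return str(v)

    rows = [tuple(norm(v) for v in row) for row in df.itertuples(index=False, name=None)]
    return sorted(rows, key=lambda r: tuple((x is None, x) for x in r))


def assert_same_rows(df1: pd.DataFrame, df2: pd.DataFrame):
    assert list(df1.columns) == list(df2.columns)
    assert row_multiset(df1) == row_multiset(df2)


@pytest.fixture
def toy_pair():
    """A tiny hand-checkable probe/build pair."""
    a = IntervalFrame(
        pd.DataFrame(
            {
                "contig": ["chr1", "chr1", "chr2"],
                "start": [0, 150, 10],
                "end": [100, 250, 20],
                "name": ["a1", "a2", "a3"],
            }
        )
    )
    b = IntervalFrame(
        pd.DataFrame(
            {
                "contig": ["chr1", "chr1"],
                "start": [90, 300],
                "end": [160, 400],
                "name": ["b1", "b2"],
            }
        )
    )
    return a, b
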