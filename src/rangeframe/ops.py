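"""Table-level range operations: overlap, nearest, count_overlaps, coverage.

Each operation takes two :class:`~rangeframe.frame.IntervalFrame` objects —
``a``, the *probe* side (each of whose rows drives a query), and ``b``, the
*build* side (turned into a search index) — and returns a joined result
frame.  The result carries the probe columns suffixed ``"_1"``, the build
columns suffixed ``"_2"`` where applicable, and operation-specific columns:

========================  =======================================================
operation                 extra columns
========================  =======================================================
``overlap``               none (one row per overlapping pair)
``nearest``               ``distance`` — gap in base pairs (0 = overlap or touch)
``count_overlaps``        ``count`` — overlapping build rows per probe row
``coverage``              ``covered`` (base pairs), ``coverage_fraction``
========================  =======================================================

Coordinate handling: the two inputs may use different conventions; both are
normalized to half-open internally and the output is expressed in the probe
frame's convention.  The pairing produced is therefore independent of how the
inputs were encoded.

``b`` is always the indexed side, matching the "for each interval a in A"
reading of the operations; no automatic side-swapping by size is performed.
For repeated probes against the same build side, construct a
:class:`BuildEngine` once and pass it as ``engine=``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _kernels
from .errors import CoordinateError
from .frame import (
    CoordSystem,
    IntervalFrame,
    merge_intervals,
    require_valid,
    to_half_open,
)
from .index import IntervalIndex

__all__ = ["BuildEngine", "overlap", "nearest", "count_overlaps", "coverage"]


class BuildEngine:
    """Materialized state for the build side of a join: index + merged union.

    Construct once, reuse across many probe frames (this is what streaming
    execution does: only this object and one probe batch are resident).
    """

    def __init__(self, b: IntervalFrame):
        require_valid(b)
        self.frame = b
        self.half_open = to_half_open(b)
        self.index = IntervalIndex(self.half_open)
        self._cov: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    @property
    def n_rows(self) -> int:
        return self.half_open.n_rows

    def coverage_arrays(self, contig: str):
        """Disjoint merged intervals of the build side on ``contig`` plus a
        cumulative-length table: ``cum[j]`` = total merged bases before
        component ``j``."""
        if self._cov is None:
            merged = merge_intervals(self.half_open)
            c = merged.contigs.astype(str)
            s = merged.starts.astype(np.int64)
            e = merged.ends.astype(np.int64)
            self._cov = {}
            if len(c):
                cut = np.flatnonzero(c[1:] != c[:-1]) + 1
                blocks = np.concatenate(([0], cut, [len(c)]))
                for lo, hi in zip(blocks[:-1], blocks[1:]):
                    ms, me = s[lo:hi], e[lo:hi]
                    cum = np.zeros(len(ms) + 1, dtype=np.int64)
                    np.cumsum(me - ms, out=cum[1:])
                    self._cov[str(c[lo])] = (ms, me, cum)
        return self._cov.get(contig)


# ---------------------------------------------------------------------------
# result assembly helpers


def _null_dtype(dt):
    if pd.api.types.is_extension_array_dtype(dt):
        return dt
    if pd.api.types.is_integer_dtype(dt):
        return pd.Int64Dtype()
    if pd.api.types.is_bool_dtype(dt):
        return pd.BooleanDtype()
    if pd.api.types.is_float_dtype(dt):
        return dt
    return np.dtype(object)


def _take_with_nulls(df: pd.DataFrame, idx: np.ndarray, mask: np.ndarray) -> pd.DataFrame:
    """``df.iloc[idx]`` with rows where ``mask`` is set replaced by nulls."""
    idx = np.asarray(idx, dtype=np.int64)
    mask = np.asarray(mask, dtype=bool)
    if len(df) == 0:
        return pd.DataFrame(
            {c: pd.array([pd.NA] * len(idx), dtype=_null_dtype(df[c].dtype)) for c in df.columns}
        )
    safe = idx.copy()
    safe[mask] = 0
    out = df.iloc[safe].reset_index(drop=True)
    if mask.any():
        for col in out.columns:
            dt = out[col].dtype
            ndt = _null_dtype(dt)
            if ndt is not dt and ndt != dt:
                out[col] = out[col].astype(ndt)
        out.loc[mask] = pd.NA
    return out


def _convert_taken_coords(starts: np.ndarray, ends: np.ndarray, target: CoordSystem):
    """Half-open coordinate arrays re-expressed in ``target``."""
    if target is CoordSystem.ZERO_BASED_HALF_OPEN:
        return starts, ends
    zl = np.flatnonzero(starts == ends)
    if zl.size:
        raise CoordinateError(
            "matched zero-length build interval(s) cannot be represented in "
            "one_based_closed output coordinates"
        )
    return starts + 1, ends


def _build_side_frame(
    engine: BuildEngine,
    rid: np.ndarray,
    mask: np.ndarray,
    target: CoordSystem,
    suffix: str,
) -> pd.DataFrame:
    """Build-side output columns for matched rows ``rid`` (``mask`` = no match)."""
    b = engine.frame
    c_col, s_col, e_col = b.cols
    payload = engine.frame.data.drop(columns=[s_col, e_col])
    out = _take_with_nulls(payload, rid, mask)

    bs = engine.half_open.data[s_col].to_numpy(dtype=np.int64)
    be = engine.half_open.data[e_col].to_numpy(dtype=np.int64)
    safe = np.where(mask, 0, rid) if len(bs) else np.zeros(len(rid), dtype=np.int64)
    if len(bs):
        ts, te = _convert_taken_coords(bs[safe][~mask], be[safe][~mask], target)
        s_vals = np.zeros(len(rid), dtype=np.int64)
        e_vals = np.zeros(len(rid), dtype=np.int64)
        s_vals[~mask] = ts
        e_vals[~mask] = te
    else:
        s_vals = np.zeros(len(rid), dtype=np.int64)
        e_vals = np.zeros(len(rid), dtype=np.int64)
    if mask.any():
        s_arr = pd.array(s_vals, dtype="Int64")
        e_arr = pd.array(e_vals, dtype="Int64")
        s_arr[mask] = pd.NA
        e_arr[mask] = pd.NA
    else:
        s_arr, e_arr = s_vals, e_vals

    cols = {}
    for name in b.data.columns:
        if name == s_col:
            cols[name + suffix] = s_arr
        elif name == e_col:
            cols[name + suffix] = e_arr
        else:
            cols[name + suffix] = out[name].to_numpy() if out[name].dtype == object else out[name]
    return pd.DataFrame(cols)


def _probe_side_frame(a: IntervalFrame, idx: np.ndarray, suffix: str) -> pd.DataFrame:
    out = a.data.iloc[np.asarray(idx, dtype=np.int64)].reset_index(drop=True)
    out.columns = [c + suffix for c in out.columns]
    return out


def _result_frame(df: pd.DataFrame, a: IntervalFrame, suffix: str) -> IntervalFrame:
    c, s, e = a.cols
    return IntervalFrame(df, a.coord_system, (c + suffix, s + suffix, e + suffix))


def _probe_groups(a_ho: IntervalFrame):
    """Yield (contig, positions) groups of the probe frame, plus its arrays."""
    contigs = a_ho.contigs.astype(str)
    s = a_ho.data[a_ho.cols[1]].to_numpy(dtype=np.int64)
    e = a_ho.data[a_ho.cols[2]].to_numpy(dtype=np.int64)
    uniq, inv = np.unique(contigs, return_inverse=True)
    groups = [(str(u), np.flatnonzero(inv == i)) for i, u in enumerate(uniq)]
    return groups, s, e


def _as_engine(b) -> BuildEngine:
    return b if isinstance(b, BuildEngine) else BuildEngine(b)


# ---------------------------------------------------------------------------
# operations


def overlap(
    a: IntervalFrame,
    b: "IntervalFrame | BuildEngine",
    how: str = "inner",
    suffixes: tuple[str, str] = ("_1", "_2"),
    sort_output: bool = True,
    engine: BuildEngine | None = None,
) -> IntervalFrame:
    """Join ``a`` against ``b`` on interval overlap.

    ``how="inner"`` emits one row per overlapping pair; ``how="left"``
    additionally emits one row (build columns null) for every probe row with
    no overlap.  With ``sort_output`` the rows are ordered by (probe row,
    build row); otherwise order is unspecified.
    """
    if how not in ("inner", "left"):
        raise ValueError(f"how must be 'inner' or 'left', got {how!r}")
    eng = engine if engine is not None else _as_engine(b)
    require_valid(a)
    a_ho = to_half_open(a)
    groups, s, e = _probe_groups(a_ho)

    q_parts: list[np.ndarray] = []
    b_parts: list[np.ndarray] = []
    hit_counts = np.zeros(a_ho.n_rows, dtype=np.int64)
    for contig, pos in groups:
        cl = eng.index.contig_arrays(contig)
        if cl is None:
            continue
        qs = s[pos]
        qe = np.maximum(e[pos], qs + 1)
        counts, oq, ob = _kernels.overlap_pairs_arrays(qs, qe, cl)
        hit_counts[pos] = counts
        q_parts.append(pos[oq])
        b_parts.append(ob)

    qpos = np.concatenate(q_parts) if q_parts else np.zeros(0, dtype=np.int64)
    brid = np.concatenate(b_parts) if b_parts else np.zeros(0, dtype=np.int64)

    if how == "left":
        miss = np.flatnonzero(hit_counts == 0)
        qpos = np.concatenate([qpos, miss])
        brid = np.concatenate([brid, np.full(len(miss), -1, dtype=np.int64)])

    if sort_output:
        order = np.lexsort((brid, qpos))
        qpos, brid = qpos[order], brid[order]

    mask = brid < 0
    left_df = _probe_side_frame(a, qpos, suffixes[0])
    right_df = _build_side_frame(eng, brid, mask, a.coord_system, suffixes[1])
    out = pd.concat([left_df, right_df], axis=1)
    return _result_frame(out, a, suffixes[0])


def count_overlaps(
    a: IntervalFrame,
    b: "IntervalFrame | BuildEngine",
    suffixes: tuple[str, str] = ("_1", "_2"),
    engine: BuildEngine | None = None,
) -> IntervalFrame:
    """Per probe row, the number of build intervals overlapping it.

    Emits exactly ``len(a)`` rows in probe order with an integer ``count``
    column (zeros included).
    """
    eng = engine if engine is not None else _as_engine(b)
    require_valid(a)
    a_ho = to_half_open(a)
    groups, s, e = _probe_groups(a_ho)
    counts = np.zeros(a_ho.n_rows, dtype=np.int64)
    for contig, pos in groups:
        cl = eng.index.contig_arrays(contig)
        if cl is None:
            continue
        qs = s[pos]
        qe = np.maximum(e[pos], qs + 1)
        counts[pos] = _kernels.count_overlaps_arrays(qs, qe, cl)
    out = _probe_side_frame(a, np.arange(a_ho.n_rows), suffixes[0])
    out["count"] = counts
    return _result_frame(out, a, suffixes[0])


def coverage(
    a: IntervalFrame,
    b: "IntervalFrame | BuildEngine",
    suffixes: tuple[str, str] = ("_1", "_2"),
    engine: BuildEngine | None = None,
) -> IntervalFrame:
    """Base pairs of each probe interval covered by the union of build intervals.

    Emits exactly ``len(a)`` rows in probe order with ``covered`` (bases,
    computed against the merged build union so stacked intervals never double
    count) and ``coverage_fraction`` (``covered / probe length``; 0 for a
    zero-length probe).
    """
    eng = engine if engine is not None else _as_engine(b)
    require_valid(a)
    a_ho = to_half_open(a)
    groups, s, e = _probe_groups(a_ho)
    covered = np.zeros(a_ho.n_rows, dtype=np.int64)
    for contig, pos in groups:
        cov = eng.coverage_arrays(contig)
        if cov is None:
            continue
        ms, me, cum = cov

        def union_below(p):
            j = np.searchsorted(ms, p, side="right")
            res = cum[j].astype(np.int64)
            nz = j > 0
            jm = np.maximum(j - 1, 0)
            res -= np.where(nz, np.maximum(me[jm] - p, 0), 0)
            return res

        covered[pos] = union_below(e[pos]) - union_below(s[pos])
    length = e - s
    frac = np.zeros(a_ho.n_rows, dtype=np.float64)
    nz = length > 0
    frac[nz] = covered[nz] / length[nz]
    out = _probe_side_frame(a, np.arange(a_ho.n_rows), suffixes[0])
    out["covered"] = covered
    out["coverage_fraction"] = frac
    return _result_frame(out, a, suffixes[0])


def nearest(
    a: IntervalFrame,
    b: "IntervalFrame | BuildEngine",
    k: int = 1,
    suffixes: tuple[str, str] = ("_1", "_2"),
    sort_output: bool = True,
    engine: BuildEngine | None = None,
) -> IntervalFrame:
    """For each probe row, the ``k`` nearest build intervals on its contig.

    Left-style: every probe row appears.  A probe on a contig absent from the
    build side yields a single row with null build columns and null distance.
    ``distance`` is the half-open gap in base pairs: 0 when the pair overlaps
    or touches.  Ties break by (build start, build end, build row).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    eng = engine if engine is not None else _as_engine(b)
    require_valid(a)
    a_ho = to_half_open(a)
    contigs = a_ho.contigs.astype(str)
    s = a_ho.data[a_ho.cols[1]].to_numpy(dtype=np.int64)
    e = a_ho.data[a_ho.cols[2]].to_numpy(dtype=np.int64)

    qpos: list[int] = []
    brid: list[int] = []
    dists: list[int] = []
    for i in range(a_ho.n_rows):
        matches = eng.index.nearest((contigs[i], s[i], e[i]), k=k)
        if not matches:
            qpos.append(i)
            brid.append(-1)
            dists.append(-1)
        else:
            for rid, d in matches:
                qpos.append(i)
                brid.append(rid)
                dists.append(d)

    qpos_a = np.asarray(qpos, dtype=np.int64)
    brid_a = np.asarray(brid, dtype=np.int64)
    dist_a = np.asarray(dists, dtype=np.int64)
    # rows are emitted in probe order with non-decreasing distance per probe,
    # which is already the sorted order; sort_output kept for symmetry
    if sort_output:
        order = np.lexsort((brid_a, dist_a, qpos_a))
        qpos_a, brid_a, dist_a = qpos_a[order], brid_a[order], dist_a[order]

    mask = brid_a < 0
    left_df = _probe_side_frame(a, qpos_a, suffixes[0])
    right_df = _build_side_frame(eng, brid_a, mask, a.coord_system, suffixes[1])
    out = pd.concat([left_df, right_df], axis=1)
    if mask.any():
        d_arr = pd.array(dist_a, dtype="Int64")
        d_arr[mask] = pd.NA
        out["distance"] = d_arr
    else:
        out["distance"] = dist_a
    return _result_frame(out, a, suffixes[0])
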