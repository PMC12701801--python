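"""Immutable per-contig interval search structure.

The index is an augmented interval list: per contig, intervals are sorted by
start and stored alongside a running maximum of their end coordinates.  An
overlap query binary-searches the last start below the query end, then scans
backwards; the running maximum lets the scan stop as soon as no earlier
interval can still reach the query.  When a contig mixes many long
("covering") intervals with short ones — which would defeat the running-max
pruning — the build step decomposes the list into a small number of
components so that each component scans efficiently; queries visit every
component.

Coordinate semantics: queries and index are in canonical half-open
coordinates.  Zero-length intervals (``start == end``) on either side are
treated as points: a point ``p`` overlaps ``[s, e)`` iff ``s <= p < e``, and
two points overlap iff they coincide.  This is implemented by giving
zero-length intervals an *effective* end of ``start + 1`` in the overlap
predicate only; nearest-distance arithmetic always uses the true
coordinates.

Two intervals that merely touch (``a.end == b.start``) do **not** overlap —
they share no base — but their nearest distance is 0.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .frame import CoordSystem, GenomicInterval, IntervalFrame, to_half_open

__all__ = ["IntervalIndex", "QueryStats", "build_index", "interval_distance"]

# decomposition parameters: an interval is demoted to the next component when
# at least _COVER_MIN of the _COVER_WINDOW intervals following it (in start
# order) end before it does, i.e. it covers them and would poison the
# running-max pruning for queries landing after them
_COVER_WINDOW = 32
_COVER_MIN = 16
_MIN_COMPONENT = 64
_MAX_COMPONENTS = 8


def interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bases between two half-open intervals; 0 when they overlap or touch."""
    return max(0, b_start - a_end, a_start - b_end)


@dataclass
class QueryStats:
    """Instrumentation: work done by index queries (for complexity sanity checks)."""

    inspected: int = 0  # candidate intervals examined during scans
    bisect_steps: int = 0  # binary-search iterations

    def reset(self) -> None:
        self.inspected = 0
        self.bisect_steps = 0


@dataclass
class _ContigList:
    starts: np.ndarray  # int64, sorted within each component
    ends: np.ndarray  # true ends
    eff_ends: np.ndarray  # max(end, start + 1); overlap predicate uses these
    max_eff_ends: np.ndarray  # running max of eff_ends within each component
    row_ids: np.ndarray
    comp_bounds: np.ndarray  # component c spans [comp_bounds[c], comp_bounds[c+1])
    # lazily built, globally sorted views for nearest queries
    _nn: tuple | None = field(default=None, repr=False)

    def nn_arrays(self):
        if self._nn is None:
            by_start = np.lexsort((self.row_ids, self.ends, self.starts))
            by_end = np.lexsort((self.row_ids, self.starts, self.ends))
            self._nn = (
                self.starts[by_start],
                self.ends[by_start],
                self.row_ids[by_start],
                self.starts[by_end],
                self.ends[by_end],
                self.row_ids[by_end],
            )
        return self._nn


def _decompose(starts, ends, eff_ends, row_ids):
    """Split one contig's sorted interval list into AIList-style components."""
    comps = []
    rem = np.arange(len(starts))
    while True:
        n = rem.size
        if n <= _MIN_COMPONENT or len(comps) >= _MAX_COMPONENTS - 1:
            comps.append(rem)
            break
        e = eff_ends[rem]
        cover = np.zeros(n, dtype=np.int64)
        for off in range(1, _COVER_WINDOW + 1):
            cover[:-off] += e[off:] < e[:-off]
        demote = cover >= _COVER_MIN
        n_demoted = int(demote.sum())
        if n_demoted < _MIN_COMPONENT // 2:
            comps.append(rem)
            break
        comps.append(rem[~demote])
        rem = rem[demote]

    order = np.concatenate(comps)
    bounds = np.zeros(len(comps) + 1, dtype=np.int64)
    np.cumsum([len(c) for c in comps], out=bounds[1:])
    starts, ends, eff_ends, row_ids = (
        starts[order],
        ends[order],
        eff_ends[order],
        row_ids[order],
    )
    max_eff = eff_ends.copy()
    for c in range(len(comps)):
        lo, hi = bounds[c], bounds[c + 1]
        np.maximum.accumulate(max_eff[lo:hi], out=max_eff[lo:hi])
    return _ContigList(starts, ends, eff_ends, max_eff, row_ids, bounds)


class IntervalIndex:
    """Immutable search structure over the build side of an interval join.

    Build once with :func:`build_index` (or the constructor); query with
    :meth:`query_overlaps`, :meth:`count_overlaps` and :meth:`nearest`.
    Queries never mutate the index, so repeated identical queries return
    identical results.
    """

    def __init__(self, frame: IntervalFrame):
        ho = to_half_open(frame)
        self.source_coord_system: CoordSystem = frame.coord_system
        self.n_items: int = ho.n_rows
        self._contigs: dict[str, _ContigList] = {}

        if ho.n_rows:
            contigs = ho.data[ho.cols[0]].to_numpy()
            starts = ho.data[ho.cols[1]].to_numpy(dtype=np.int64)
            ends = ho.data[ho.cols[2]].to_numpy(dtype=np.int64)
            row_ids = np.arange(ho.n_rows, dtype=np.int64)
            eff = np.maximum(ends, starts + 1)
            order = np.lexsort((row_ids, ends, starts, contigs))
            contigs, starts, ends, eff, row_ids = (
                contigs[order],
                starts[order],
                ends[order],
                eff[order],
                row_ids[order],
            )
            # contig block boundaries in the sorted arrays
            cut = np.flatnonzero(contigs[1:] != contigs[:-1]) + 1
            blocks = np.concatenate(([0], cut, [len(contigs)]))
            for lo, hi in zip(blocks[:-1], blocks[1:]):
                name = str(contigs[lo])
                self._contigs[name] = _decompose(
                    starts[lo:hi], ends[lo:hi], eff[lo:hi], row_ids[lo:hi]
                )

    # -- introspection ---------------------------------------------------

    @property
    def contig_names(self) -> list[str]:
        return sorted(self._contigs)

    def contig_arrays(self, name: str) -> _ContigList | None:
        """Internal arrays for one contig (used by the table-level kernels)."""
        return self._contigs.get(name)

    def __len__(self) -> int:
        return self.n_items

    # -- queries ---------------------------------------------------------

    @staticmethod
    def _as_coords(q) -> tuple[str, int, int]:
        if isinstance(q, GenomicInterval):
            return q.contig, q.start, q.end
        contig, start, end = q
        return str(contig), int(start), int(end)

    def query_overlaps(self, q, stats: QueryStats | None = None) -> list[int]:
        """Row ids of build intervals sharing at least one base with ``q``.

        ``q`` is a :class:`GenomicInterval` or ``(contig, start, end)`` tuple
        in half-open coordinates.  Unknown contigs yield ``[]``.  Order of the
        returned ids is unspecified.
        """
        contig, qs, qe = self._as_coords(q)
        cl = self._contigs.get(contig)
        if cl is None:
            return []
        qe_eff = qe if qe > qs else qs + 1
        starts = cl.starts
        out: list[int] = []
        for c in range(len(cl.comp_bounds) - 1):
            lo = int(cl.comp_bounds[c])
            hi = int(cl.comp_bounds[c + 1])
            j = bisect_left(starts, qe_eff, lo, hi)
            if stats is not None and hi > lo:
                stats.bisect_steps += max(1, (hi - lo).bit_length())
            j -= 1
            while j >= lo:
                if stats is not None:
                    stats.inspected += 1
                if cl.max_eff_ends[j] <= qs:
                    break
                if cl.eff_ends[j] > qs:
                    out.append(int(cl.row_ids[j]))
                j -= 1
        return out

    def count_overlaps(self, q, stats: QueryStats | None = None) -> int:
        """Number of build intervals overlapping ``q`` (ids not materialized)."""
        contig, qs, qe = self._as_coords(q)
        cl = self._contigs.get(contig)
        if cl is None:
            return 0
        qe_eff = qe if qe > qs else qs + 1
        starts = cl.starts
        n = 0
        for c in range(len(cl.comp_bounds) - 1):
            lo = int(cl.comp_bounds[c])
            hi = int(cl.comp_bounds[c + 1])
            j = bisect_left(starts, qe_eff, lo, hi) - 1
            while j >= lo:
                if stats is not None:
                    stats.inspected += 1
                if cl.max_eff_ends[j] <= qs:
                    break
                if cl.eff_ends[j] > qs:
                    n += 1
                j -= 1
        return n

    def nearest(self, q, k: int = 1) -> list[tuple[int, int]]:
        """The ``k`` build intervals nearest to ``q`` on its contig.

        Distance is the half-open gap ``max(0, b.start - q.end, q.start -
        b.end)``: 0 for overlapping *or touching* pairs.  Ties break by
        (smaller build start, smaller build end, smaller row id).  Returns up
        to ``min(k, n_on_contig)`` pairs ``(row_id, distance)`` with
        non-decreasing distances; ``[]`` if the contig has no build interval.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        contig, qs, qe = self._as_coords(q)
        cl = self._contigs.get(contig)
        if cl is None:
            return []
        ns, ne, nrid, es_s, es_e, es_rid = cl.nn_arrays()
        n = len(ns)

        cand: dict[int, tuple[int, int, int, int]] = {}

        def add(dist, start, end, rid):
            prev = cand.get(rid)
            item = (int(dist), int(start), int(end), int(rid))
            if prev is None or item < prev:
                cand[rid] = item

        # overlapping intervals: distance 0
        overlap_rids = self.query_overlaps((contig, qs, qe))
        if overlap_rids:
            rid_order = np.argsort(nrid, kind="stable")
            sorted_rids = nrid[rid_order]
            for rid in overlap_rids:
                p = int(rid_order[np.searchsorted(sorted_rids, rid)])
                add(0, ns[p], ne[p], rid)

        # right side: starts >= qe, distance = start - qe, ascending in start
        j0 = int(np.searchsorted(ns, qe, side="left"))
        j = j0
        taken = 0
        while j < n and (taken < k or ns[j] == ns[j - 1]):
            add(ns[j] - qe, ns[j], ne[j], nrid[j])
            taken += 1
            j += 1

        # left side: ends <= qs, distance = qs - end, ascending as end descends
        j1 = int(np.searchsorted(es_e, qs, side="right"))
        j = j1 - 1
        taken = 0
        while j >= 0 and (taken < k or es_e[j] == es_e[j + 1]):
            add(qs - es_e[j], es_s[j], es_e[j], es_rid[j])
            taken += 1
            j -= 1

        best = sorted(cand.values())[:k]
        return [(rid, dist) for dist, _s, _e, rid in best]


def build_index(frame: IntervalFrame) -> IntervalIndex:
    """Build the immutable per-contig index over ``frame`` (the build side)."""
    return IntervalIndex(frame)
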