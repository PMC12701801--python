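"""Hot query loops, JIT-compiled with numba when available.

Each kernel is written as plain Python over numpy arrays so the same code
runs uncompiled (correct, slower) if numba cannot be imported.  Arrays follow
the index layout: per-contig starts sorted within each component, effective
ends (zero-length intervals inflated to one base for the overlap predicate),
and a running maximum of effective ends per component for scan pruning.
"""

from __future__ import annotations

import numpy as np


def _count_overlaps_kernel(qs, qe, bs, beff, bmax, comps, counts):
    nq = qs.shape[0]
    ncomp = comps.shape[0] - 1
    for i in range(nq):
        qsv = qs[i]
        qev = qe[i]
        c = 0
        for ci in range(ncomp):
            lo = comps[ci]
            hi = comps[ci + 1]
            l = lo
            h = hi
            while l < h:
                m = (l + h) >> 1
                if bs[m] < qev:
                    l = m + 1
                else:
                    h = m
            j = l - 1
            while j >= lo and bmax[j] > qsv:
                if beff[j] > qsv:
                    c += 1
                j -= 1
        counts[i] = c


def _fill_overlaps_kernel(qs, qe, bs, beff, bmax, comps, offsets, out_q, out_b):
    nq = qs.shape[0]
    ncomp = comps.shape[0] - 1
    for i in range(nq):
        qsv = qs[i]
        qev = qe[i]
        pos = offsets[i]
        for ci in range(ncomp):
            lo = comps[ci]
            hi = comps[ci + 1]
            l = lo
            h = hi
            while l < h:
                m = (l + h) >> 1
                if bs[m] < qev:
                    l = m + 1
                else:
                    h = m
            j = l - 1
            while j >= lo and bmax[j] > qsv:
                if beff[j] > qsv:
                    out_q[pos] = i
                    out_b[pos] = j
                    pos += 1
                j -= 1


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _count_overlaps_kernel = njit(cache=False)(_count_overlaps_kernel)
    _fill_overlaps_kernel = njit(cache=False)(_fill_overlaps_kernel)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def count_overlaps_arrays(qs, qe_eff, contig_list):
    """Per-query overlap counts against one contig's index arrays."""
    counts = np.zeros(qs.shape[0], dtype=np.int64)
    if contig_list is not None and qs.shape[0]:
        _count_overlaps_kernel(
            qs,
            qe_eff,
            contig_list.starts,
            contig_list.eff_ends,
            contig_list.max_eff_ends,
            contig_list.comp_bounds,
            counts,
        )
    return counts


def overlap_pairs_arrays(qs, qe_eff, contig_list):
    """All overlapping (query position, build row id) pairs for one contig.

    Returns ``(counts, q_pos, b_rid)`` where ``counts[i]`` is the number of
    hits of query ``i`` and the pair arrays are grouped by query position.
    """
    counts = count_overlaps_arrays(qs, qe_eff, contig_list)
    total = int(counts.sum())
    out_q = np.empty(total, dtype=np.int64)
    out_b = np.empty(total, dtype=np.int64)
    if total:
        offsets = np.zeros(qs.shape[0], dtype=np.int64)
        np.cumsum(counts[:-1], out=offsets[1:])
        _fill_overlaps_kernel(
            qs,
            qe_eff,
            contig_list.starts,
            contig_list.eff_ends,
            contig_list.max_eff_ends,
            contig_list.comp_bounds,
            offsets,
            out_q,
            out_b,
        )
        out_b = contig_list.row_ids[out_b]
    return counts, out_q, out_b
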