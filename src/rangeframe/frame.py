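"""Interval frames: tabular genomic intervals with explicit coordinate semantics.

An :class:`IntervalFrame` wraps a :class:`pandas.DataFrame` that has three
designated coordinate columns (contig, start, end) plus any number of payload
columns, and records which of the two genomic coordinate conventions the
numbers follow:

* ``zero_based_half_open`` — BED convention; an interval ``[s, e)`` contains
  positions ``s <= p < e`` and has length ``e - s``.  ``s == e`` is a valid
  zero-length interval (a point between bases).
* ``one_based_closed`` — GFF3/VCF convention; an interval ``s..e`` contains
  positions ``s <= p <= e`` (both 1-based) and has length ``e - s + 1``.
  Zero-length spans have no representation.

All range operations in this package convert to half-open coordinates
internally (no off-by-one corrections in the arithmetic) and restore the
caller's convention on output.

Contig names are opaque strings compared by exact equality: ``"chr1"`` and
``"1"`` are different sequences.  Duplicate rows are kept; operations are
multiset-faithful.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import CoordinateError, MissingColumnsError, ValidationError

__all__ = [
    "CoordSystem",
    "GenomicInterval",
    "IntervalFrame",
    "Violation",
    "validate_frame",
    "convert_coordinates",
    "sort_frame",
    "merge_intervals",
]

DEFAULT_COLS = ("contig", "start", "end")


class CoordSystem(str, enum.Enum):
    """The two coordinate conventions understood by this package."""

    ZERO_BASED_HALF_OPEN = "zero_based_half_open"
    ONE_BASED_CLOSED = "one_based_closed"

    @classmethod
    def coerce(cls, value: "CoordSystem | str") -> "CoordSystem":
        if isinstance(value, cls):
            return value
        v = str(value).lower().replace("-", "_")
        aliases = {
            "0based": cls.ZERO_BASED_HALF_OPEN,
            "0_based": cls.ZERO_BASED_HALF_OPEN,
            "bed": cls.ZERO_BASED_HALF_OPEN,
            "half_open": cls.ZERO_BASED_HALF_OPEN,
            "zero_based_half_open": cls.ZERO_BASED_HALF_OPEN,
            "1based": cls.ONE_BASED_CLOSED,
            "1_based": cls.ONE_BASED_CLOSED,
            "gff": cls.ONE_BASED_CLOSED,
            "closed": cls.ONE_BASED_CLOSED,
            "one_based_closed": cls.ONE_BASED_CLOSED,
        }
        try:
            return aliases[v]
        except KeyError:
            raise ValueError(f"unknown coordinate system: {value!r}") from None


class GenomicInterval(NamedTuple):
    """One contig-anchored span; ``row_id`` is its ordinal position in the source frame."""

    contig: str
    start: int
    end: int
    row_id: int = 0

    def length(self, coord_system: CoordSystem = CoordSystem.ZERO_BASED_HALF_OPEN) -> int:
        if coord_system is CoordSystem.ONE_BASED_CLOSED:
            return self.end - self.start + 1
        return self.end - self.start


@dataclass(frozen=True)
class Violation:
    """A row-level breach of the coordinate-system invariants."""

    row_id: int
    reason: str


class IntervalFrame:
    """A table of genomic intervals plus payload columns.

    Parameters
    ----------
    data
        Any mapping/records accepted by ``pd.DataFrame`` or a DataFrame.
        The row index is discarded: row ``i`` of the frame has implicit
        ``row_id == i``.
    coord_system
        Coordinate convention of the ``start``/``end`` columns.
    cols
        Names of the (contig, start, end) columns. Every other column is
        payload and passes through operations unchanged.
    """

    def __init__(
        self,
        data,
        coord_system: CoordSystem | str = CoordSystem.ZERO_BASED_HALF_OPEN,
        cols: Sequence[str] = DEFAULT_COLS,
    ):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(data)
        cols = tuple(cols)
        if len(cols) != 3:
            raise ValueError("cols must name exactly (contig, start, end)")
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise MissingColumnsError(missing)
        self.data = data.reset_index(drop=True)
        self.coord_system = CoordSystem.coerce(coord_system)
        self.cols = cols

    # -- basic accessors -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def contigs(self) -> np.ndarray:
        return self.data[self.cols[0]].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.data[self.cols[1]].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.data[self.cols[2]].to_numpy()

    @property
    def payload_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.cols]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"IntervalFrame({self.n_rows} rows, {self.coord_system.value}, "
            f"cols={self.cols}, payload={self.payload_columns})"
        )

    def intervals(self) -> Iterable[GenomicInterval]:
        """Iterate rows as :class:`GenomicInterval` (row_id = position)."""
        c, s, e = (self.data[x].to_numpy() for x in self.cols)
        for i in range(len(self.data)):
            yield GenomicInterval(str(c[i]), int(s[i]), int(e[i]), i)

    # -- operations (also exposed as module functions) -------------------

    def validate(self) -> list[Violation]:
        return validate_frame(self)

    def convert(self, target: CoordSystem | str) -> "IntervalFrame":
        return convert_coordinates(self, target)

    def sort(self) -> "IntervalFrame":
        return sort_frame(self)

    def merge(self, min_gap: int = 0) -> "IntervalFrame":
        return merge_intervals(self, min_gap=min_gap)

    def copy(self) -> "IntervalFrame":
        return IntervalFrame(self.data.copy(), self.coord_system, self.cols)


def _coord_arrays(frame: IntervalFrame):
    s = frame.data[frame.cols[1]]
    e = frame.data[frame.cols[2]]
    return s, e


def validate_frame(frame: IntervalFrame) -> list[Violation]:
    """Check every row against the frame's coordinate-system invariants.

    Returns an empty list iff the frame is valid.  Each violation carries the
    offending ``row_id`` and a human-readable reason.  A missing coordinate
    column is a structural error (:class:`MissingColumnsError`, raised by the
    :class:`IntervalFrame` constructor) and never appears here.
    """
    violations: list[Violation] = []
    contig = frame.data[frame.cols[0]]
    s_col, e_col = _coord_arrays(frame)

    null_contig = contig.isna().to_numpy()
    for i in np.flatnonzero(null_contig):
        violations.append(Violation(int(i), "null contig"))

    def numeric(col, name):
        vals = pd.to_numeric(col, errors="coerce")
        bad_null = col.isna().to_numpy()
        bad_nonnum = (~bad_null) & vals.isna().to_numpy()
        ok = ~(bad_null | bad_nonnum)
        frac = vals.to_numpy(dtype=float, na_value=np.nan)
        nonint = ok & (np.floor(np.nan_to_num(frac)) != np.nan_to_num(frac))
        out = np.full(len(col), np.iinfo(np.int64).min, dtype=np.int64)
        usable = ok & ~nonint
        out[usable] = frac[usable].astype(np.int64)
        reasons = {}
        for i in np.flatnonzero(bad_null):
            reasons[int(i)] = f"null {name}"
        for i in np.flatnonzero(bad_nonnum | nonint):
            reasons[int(i)] = f"non-integer {name}"
        return out, usable, reasons

    s, s_ok, s_reasons = numeric(s_col, "start")
    e, e_ok, e_reasons = numeric(e_col, "end")
    for i, r in sorted({**s_reasons, **e_reasons}.items()):
        violations.append(Violation(i, r))

    both = s_ok & e_ok
    lo = 0 if frame.coord_system is CoordSystem.ZERO_BASED_HALF_OPEN else 1
    for i in np.flatnonzero(both & (s < lo)):
        violations.append(Violation(int(i), f"start < {lo}"))
    for i in np.flatnonzero(both & (s >= lo) & (s > e)):
        violations.append(Violation(int(i), "start > end"))
    violations.sort(key=lambda v: v.row_id)
    return violations


def require_valid(frame: IntervalFrame) -> None:
    """Raise :class:`ValidationError` unless the frame is valid."""
    v = validate_frame(frame)
    if v:
        raise ValidationError(v)


def convert_coordinates(frame: IntervalFrame, target: CoordSystem | str) -> IntervalFrame:
    """Re-express coordinates in ``target``; payload untouched; round-trip exact.

    1-based closed ``(s, e)`` maps to half-open ``(s-1, e)`` and back.
    A zero-length half-open interval (``start == end``) has no 1-based
    closed representation; converting one raises :class:`CoordinateError`.
    """
    target = CoordSystem.coerce(target)
    if target is frame.coord_system:
        return IntervalFrame(frame.data.copy(), frame.coord_system, frame.cols)
    df = frame.data.copy()
    s_name = frame.cols[1]
    s = df[s_name].to_numpy()
    if target is CoordSystem.ZERO_BASED_HALF_OPEN:
        df[s_name] = s - 1
    else:
        e = df[frame.cols[2]].to_numpy()
        zero_len = np.flatnonzero(s == e)
        if zero_len.size:
            raise CoordinateError(
                "zero-length interval(s) at row(s) "
                f"{zero_len[:5].tolist()} cannot be represented in "
                "one_based_closed coordinates"
            )
        df[s_name] = s + 1
    return IntervalFrame(df, target, frame.cols)


def to_half_open(frame: IntervalFrame) -> IntervalFrame:
    """Canonical internal form (identity if already half-open)."""
    return convert_coordinates(frame, CoordSystem.ZERO_BASED_HALF_OPEN)


def sort_frame(frame: IntervalFrame) -> IntervalFrame:
    """Stable sort by (contig lexicographic, start, end); ties keep input order."""
    c, s, e = frame.cols
    df = frame.data.sort_values([c, s, e], kind="mergesort", ignore_index=True)
    return IntervalFrame(df, frame.coord_system, frame.cols)


def merge_intervals(frame: IntervalFrame, min_gap: int = 0) -> IntervalFrame:
    """Collapse each contig's intervals into the minimal disjoint set covering their union.

    Overlapping intervals always merge; adjacent half-open intervals
    (``end_i == start_j``) merge when ``min_gap == 0``; intervals separated by
    a gap of fewer than ``min_gap`` bases also merge.  Payload columns are
    dropped (a merged interval has no single source row).  Output is sorted
    and expressed in the caller's coordinate system.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    ho = to_half_open(frame)
    c_name, s_name, e_name = ho.cols
    contigs = ho.data[c_name].to_numpy()
    s = ho.data[s_name].to_numpy(dtype=np.int64)
    e = ho.data[e_name].to_numpy(dtype=np.int64)

    order = np.lexsort((e, s, contigs))
    contigs, s, e = contigs[order], s[order], e[order]

    out_c: list = []
    out_s: list[int] = []
    out_e: list[int] = []
    # merge iff gap < max(min_gap, 1): gap <= 0 always merges; positive gaps
    # merge only when strictly below min_gap
    thresh = max(min_gap, 1)
    n = len(s)
    i = 0
    while i < n:
        j = i
        cur_end = e[i]
        while j + 1 < n and contigs[j + 1] == contigs[i] and s[j + 1] - cur_end < thresh:
            j += 1
            if e[j] > cur_end:
                cur_end = e[j]
        out_c.append(contigs[i])
        out_s.append(int(s[i]))
        out_e.append(int(cur_end))
        i = j + 1

    merged = IntervalFrame(
        pd.DataFrame(
            {c_name: out_c, s_name: np.asarray(out_s, dtype=np.int64), e_name: np.asarray(out_e, dtype=np.int64)}
        ),
        CoordSystem.ZERO_BASED_HALF_OPEN,
        ho.cols,
    )
    return convert_coordinates(merged, frame.coord_system)
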