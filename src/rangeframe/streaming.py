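"""Out-of-core execution: stream the probe side in bounded batches.

Only the build side of an interval operation must be materialized (it becomes
the search index); the probe side can be consumed as a sequence of bounded
row batches, with each batch's results emitted before the next batch is read.
Peak resident probe state is therefore one batch, regardless of probe size.
All four operations in this package are per-probe-row, so streaming results
are exactly the eager results (as a row multiset; concatenated batch outputs
are even in the same order as a sorted eager run, since batches are
consecutive row slices).

Typical use::

    plan = StreamPlan("overlap", build_frame=b, probe_source=scan_file("big.bed"))
    for chunk in execute_streaming(plan):
        sink.write(chunk)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

import pandas as pd

from . import io as _io
from . import ops as _ops
from .errors import ValidationError
from .frame import CoordSystem, IntervalFrame, validate_frame

__all__ = [
    "Batch",
    "StreamPlan",
    "StreamStats",
    "iter_frame_batches",
    "scan_file",
    "execute_streaming",
    "TableSink",
]

DEFAULT_BATCH_SIZE = 65536

OPERATIONS: dict[str, Callable] = {
    "overlap": _ops.overlap,
    "nearest": _ops.nearest,
    "count_overlaps": _ops.count_overlaps,
    "coverage": _ops.coverage,
}


@dataclass
class Batch:
    """A contiguous row slice of a probe frame."""

    data: pd.DataFrame
    batch_index: int
    is_last: bool
    coord_system: CoordSystem = CoordSystem.ZERO_BASED_HALF_OPEN
    cols: tuple = ("contig", "start", "end")

    @property
    def n_rows(self) -> int:
        return len(self.data)


@dataclass
class StreamStats:
    """Instrumentation for the memory contract of streaming execution."""

    peak_probe_rows: int = 0  # largest probe batch held at once
    peak_buffered_rows: int = 0  # largest parse buffer inside scan_file
    batches_in: int = 0
    batches_out: int = 0
    rows_out: int = 0

    def _saw_probe(self, n: int) -> None:
        self.batches_in += 1
        self.peak_probe_rows = max(self.peak_probe_rows, n)


@dataclass
class StreamPlan:
    """Everything needed to run one operation out-of-core.

    ``probe_source`` is any iterable of :class:`Batch` (see
    :func:`iter_frame_batches` and :func:`scan_file`).  ``sink``, if given,
    receives each output chunk via ``sink.write(frame)``.
    """

    operation: str
    build_frame: "IntervalFrame | _ops.BuildEngine"
    probe_source: Iterable[Batch]
    batch_size: int = DEFAULT_BATCH_SIZE
    sink: "TableSink | None" = None
    op_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.operation not in OPERATIONS:
            raise ValueError(
                f"unknown operation {self.operation!r}; expected one of {sorted(OPERATIONS)}"
            )
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def iter_frame_batches(frame: IntervalFrame, batch_size: int = DEFAULT_BATCH_SIZE) -> Iterator[Batch]:
    """Slice an in-memory frame into consecutive batches of ``batch_size`` rows."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    n = frame.n_rows
    if n == 0:
        return
    for bi, lo in enumerate(range(0, n, batch_size)):
        hi = min(lo + batch_size, n)
        yield Batch(
            frame.data.iloc[lo:hi].reset_index(drop=True),
            batch_index=bi,
            is_last=hi >= n,
            coord_system=frame.coord_system,
            cols=frame.cols,
        )


def scan_file(
    path,
    format: str | None = None,
    batch_size: int = DEFAULT_BATCH_SIZE,
    stats: StreamStats | None = None,
) -> Iterator[Batch]:
    """Lazily parse a BED/GFF3/VCF file into batches.

    At most one batch of parsed rows is buffered at a time; the concatenation
    of all batches equals the eager read of the same file.  A malformed line
    raises :class:`~rangeframe.errors.ParseError` (naming the line) after all
    complete batches before it have been yielded.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    fmt = format or _io.detect_format(path)
    if fmt not in _io._RECORD_ITERATORS:
        raise ValueError(f"scan_file supports bed/gff3/vcf, got {fmt!r}")
    coord = _io.FORMAT_COORD_SYSTEMS[fmt]

    def make(buf: list[list], bi: int, last: bool) -> Batch:
        frame = _io.rows_to_frame(fmt, buf)
        return Batch(frame.data, bi, last, coord, frame.cols)

    def gen() -> Iterator[Batch]:
        it = _io._RECORD_ITERATORS[fmt](path)
        buf: list[list] = []
        bi = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                if buf:
                    yield make(buf, bi, True)
                return
            except Exception:
                # flush the completed batch before surfacing the parse error
                if len(buf) == batch_size:
                    yield make(buf, bi, False)
                raise
            if len(buf) == batch_size:
                yield make(buf, bi, False)
                buf = []
                bi += 1
            buf.append(rec[1])
            if stats is not None:
                stats.peak_buffered_rows = max(stats.peak_buffered_rows, len(buf))

    return gen()


def execute_streaming(plan: StreamPlan, stats: StreamStats | None = None) -> Iterator[IntervalFrame]:
    """Run ``plan.operation`` with the probe side streamed batch by batch.

    Yields one result frame per probe batch as soon as that batch has been
    processed; the concatenated results equal the eager result on the whole
    probe frame as a row multiset.  A batch violating its coordinate-system
    invariants aborts the stream with :class:`ValidationError`; output already
    yielded (or written to the sink) stays as is.
    """
    op = OPERATIONS[plan.operation]
    engine = (
        plan.build_frame
        if isinstance(plan.build_frame, _ops.BuildEngine)
        else _ops.BuildEngine(plan.build_frame)
    )
    for batch in plan.probe_source:
        if stats is not None:
            stats._saw_probe(batch.n_rows)
        probe = IntervalFrame(batch.data, batch.coord_system, batch.cols)
        violations = validate_frame(probe)
        if violations:
            raise ValidationError(violations)
        result = op(probe, engine, engine=engine, **plan.op_kwargs)
        if stats is not None:
            stats.batches_out += 1
            stats.rows_out += result.n_rows
        if plan.sink is not None:
            plan.sink.write(result)
        yield result


class TableSink:
    """Appending TSV/CSV writer for streamed results (header written once)."""

    def __init__(self, path, format: str = "tsv"):
        if format not in ("tsv", "csv"):
            raise ValueError(f"unsupported output format: {format!r}")
        self.path = path
        self.sep = "\t" if format == "tsv" else ","
        self._fh = None
        self._wrote_header = False

    def _handle(self):
        if self._fh is None:
            import sys

            self._fh = sys.stdout if str(self.path) == "-" else open(self.path, "w", encoding="utf-8")
        return self._fh

    def write(self, frame: IntervalFrame) -> None:
        frame.data.to_csv(
            self._handle(),
            sep=self.sep,
            index=False,
            header=not self._wrote_header,
            na_rep="",
        )
        self._wrote_header = True

    def close(self) -> None:
        if self._fh is not None and self._fh is not __import__("sys").stdout:
            self._fh.close()
        self._fh = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
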