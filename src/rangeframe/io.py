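"""Readers and writers for standard genomic interval formats.

Readers return an :class:`~rangeframe.frame.IntervalFrame` tagged with the
format's native coordinate convention:

* BED — 0-based half-open (``chromStart``/``chromEnd``);
* GFF3 — 1-based closed;
* VCF — 1-based closed, where a record's interval is the span of its REF
  allele: ``start = POS``, ``end = POS + len(REF) - 1``.  INFO ``END`` tags
  and symbolic ALT alleles (``<DEL>`` etc.) are *not* interpreted; the REF
  span rule applies uniformly (documented limitation).

All readers accept plain or gzip-compressed input (sniffed from the magic
bytes), tolerate LF or CRLF line endings, and report parse failures with the
offending 1-based line number.  Row order equals file order, so implicit row
ids are stable across eager reads and batched scans.
"""

from __future__ import annotations

import gzip
import io as _io
import sys
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ParseError
from .frame import CoordSystem, IntervalFrame

__all__ = [
    "read_bed",
    "read_gff3",
    "read_vcf",
    "read_file",
    "write_table",
    "detect_format",
    "FORMAT_COORD_SYSTEMS",
]

FORMAT_COORD_SYSTEMS = {
    "bed": CoordSystem.ZERO_BASED_HALF_OPEN,
    "gff3": CoordSystem.ONE_BASED_CLOSED,
    "vcf": CoordSystem.ONE_BASED_CLOSED,
    "tsv": CoordSystem.ZERO_BASED_HALF_OPEN,
    "csv": CoordSystem.ZERO_BASED_HALF_OPEN,
}

_BED_OPTIONAL = [
    "name",
    "score",
    "strand",
    "thickStart",
    "thickEnd",
    "itemRgb",
    "blockCount",
    "blockSizes",
    "blockStarts",
]

_GFF3_COLUMNS = [
    "contig",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]

_VCF_COLUMNS = ["contig", "start", "end", "id", "ref", "alt", "qual", "filter", "info"]


def open_text(path):
    """Open ``path`` as UTF-8 text, transparently decompressing gzip."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def detect_format(path) -> str:
    """Guess a format from the file extension (``.gz`` peeled)."""
    name = str(path).lower()
    if name.endswith(".gz"):
        name = name[:-3]
    for ext, fmt in ((".bed", "bed"), (".gff3", "gff3"), (".gff", "gff3"),
                     (".vcf", "vcf"), (".tsv", "tsv"), (".csv", "csv")):
        if name.endswith(ext):
            return fmt
    raise ValueError(f"cannot infer format from file name: {path}")


# ---------------------------------------------------------------------------
# line-level record iterators (shared by eager readers and batched scans)


def iter_bed_records(path) -> Iterator[tuple[int, list]]:
    """Yield ``(lineno, [contig, start, end, *extras])`` for each BED data line."""
    with open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated toy files
                fields = line.split()
            if len(fields) < 3:
                raise ParseError(path, lineno, f"BED line has {len(fields)} column(s), need >= 3")
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                raise ParseError(
                    path, lineno, f"non-integer BED coordinates: {fields[1]!r}, {fields[2]!r}"
                ) from None
            if start < 0 or start > end:
                raise ParseError(path, lineno, f"invalid BED interval [{start}, {end})")
            yield lineno, [fields[0], start, end, *fields[3:]]


def iter_gff3_records(path) -> Iterator[tuple[int, list]]:
    """Yield GFF3 feature rows; parsing halts at a ``##FASTA`` trailer."""
    with open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"GFF3 line has {len(fields)} column(s), need 9")
            try:
                start = int(fields[3])
                end = int(fields[4])
            except ValueError:
                raise ParseError(
                    path, lineno, f"non-integer GFF3 coordinates: {fields[3]!r}, {fields[4]!r}"
                ) from None
            score = None if fields[5] == "." else float(fields[5])
            phase = None if fields[7] == "." else fields[7]
            yield lineno, [
                fields[0],
                fields[1],
                fields[2],
                start,
                end,
                score,
                fields[6],
                phase,
                fields[8],
            ]


def iter_vcf_records(path) -> Iterator[tuple[int, list]]:
    """Yield VCF records as interval rows (REF-span rule); samples ignored."""
    with open_text(path) as fh:
        saw_header = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if line.startswith("#"):
                continue
            if not saw_header:
                raise ParseError(path, lineno, "VCF data line before #CHROM header")
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(path, lineno, f"VCF line has {len(fields)} column(s), need >= 8")
            try:
                pos = int(fields[1])
            except ValueError:
                raise ParseError(path, lineno, f"non-integer POS: {fields[1]!r}") from None
            ref = fields[3]
            qual = None if fields[5] == "." else float(fields[5])
            yield lineno, [
                fields[0],
                pos,
                pos + max(len(ref), 1) - 1,
                fields[2],
                ref,
                fields[4],
                qual,
                fields[6],
                fields[7],
            ]


# ---------------------------------------------------------------------------
# frame construction


def _bed_frame(rows: list[list]) -> IntervalFrame:
    ncol = max((len(r) for r in rows), default=3)
    names = ["contig", "start", "end"]
    for i in range(3, ncol):
        names.append(_BED_OPTIONAL[i - 3] if i - 3 < len(_BED_OPTIONAL) else f"bed{i + 1}")
    cols: dict[str, list] = {n: [] for n in names}
    for r in rows:
        for i, n in enumerate(names):
            cols[n].append(r[i] if i < len(r) else None)
    df = pd.DataFrame(cols)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if "score" in df.columns and len(df):
        as_num = pd.to_numeric(df["score"], errors="coerce")
        present = df["score"].notna()
        if (as_num[present].notna()).all() and (as_num[present] % 1 == 0).all():
            if present.all():
                df["score"] = as_num.astype(np.int64)
            else:
                df["score"] = as_num.astype("Int64")
    return IntervalFrame(df, CoordSystem.ZERO_BASED_HALF_OPEN)


def _gff3_frame(rows: list[list]) -> IntervalFrame:
    df = pd.DataFrame(rows, columns=_GFF3_COLUMNS)
    if df.empty:
        df = pd.DataFrame({c: [] for c in _GFF3_COLUMNS})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["score"] = df["score"].astype(np.float64)
    return IntervalFrame(df, CoordSystem.ONE_BASED_CLOSED)


def _vcf_frame(rows: list[list]) -> IntervalFrame:
    df = pd.DataFrame(rows, columns=_VCF_COLUMNS)
    if df.empty:
        df = pd.DataFrame({c: [] for c in _VCF_COLUMNS})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["qual"] = df["qual"].astype(np.float64)
    return IntervalFrame(df, CoordSystem.ONE_BASED_CLOSED)


_RECORD_ITERATORS = {
    "bed": iter_bed_records,
    "gff3": iter_gff3_records,
    "vcf": iter_vcf_records,
}

_FRAME_BUILDERS = {
    "bed": _bed_frame,
    "gff3": _gff3_frame,
    "vcf": _vcf_frame,
}


def rows_to_frame(fmt: str, rows: list[list]) -> IntervalFrame:
    """Assemble parsed record rows of format ``fmt`` into a frame."""
    return _FRAME_BUILDERS[fmt](rows)


def read_bed(path) -> IntervalFrame:
    """Read BED3+ into a half-open frame; optional columns become payload."""
    return _bed_frame([r for _, r in iter_bed_records(path)])


def read_gff3(path) -> IntervalFrame:
    """Read GFF3 into a 1-based closed frame; attributes kept as raw strings."""
    return _gff3_frame([r for _, r in iter_gff3_records(path)])


def read_vcf(path) -> IntervalFrame:
    """Read VCF 4.x into a 1-based closed frame using the REF-span rule."""
    return _vcf_frame([r for _, r in iter_vcf_records(path)])


def read_tsv(path, sep: str = "\t", coord_system=CoordSystem.ZERO_BASED_HALF_OPEN) -> IntervalFrame:
    """Read a delimited table with contig/start/end columns (header required)."""
    df = pd.read_csv(path, sep=sep)
    return IntervalFrame(df, coord_system)


def read_file(path, format: str | None = None) -> IntervalFrame:
    """Read any supported format, auto-detecting from the extension."""
    fmt = format or detect_format(path)
    if fmt == "bed":
        return read_bed(path)
    if fmt == "gff3":
        return read_gff3(path)
    if fmt == "vcf":
        return read_vcf(path)
    if fmt in ("tsv", "csv"):
        return read_tsv(path, sep="\t" if fmt == "tsv" else ",")
    raise ValueError(f"unsupported format: {format!r}")


def write_table(result: IntervalFrame, path, format: str = "tsv") -> None:
    """Write a frame as TSV/CSV: header row, nulls as empty fields.

    ``path`` may be ``"-"`` for standard output.
    """
    if format not in ("tsv", "csv"):
        raise ValueError(f"unsupported output format: {format!r}")
    sep = "\t" if format == "tsv" else ","
    target = sys.stdout if str(path) == "-" else path
    result.data.to_csv(target, sep=sep, index=False, na_rep="")


def write_bed(frame: IntervalFrame, path) -> None:
    """Write a frame as BED (coordinates converted to half-open, no header)."""
    from .frame import to_half_open

    ho = to_half_open(frame)
    cols = [*ho.cols, *[c for c in ho.data.columns if c not in ho.cols]]
    target = sys.stdout if str(path) == "-" else path
    ho.data[cols].to_csv(target, sep="\t", index=False, header=False, na_rep=".")
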