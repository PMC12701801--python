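"""Exception types shared across the package."""

from __future__ import annotations


class RangeFrameError(Exception):
    """Base class for all rangeframe errors."""


class MissingColumnsError(RangeFrameError):
    """A designated coordinate column is absent from the table.

    This is a structural defect of the frame, distinct from row-level
    coordinate violations (which are reported as :class:`Violation`
    records by ``validate_frame``).
    """

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"missing coordinate column(s): {', '.join(self.missing)}")


class ValidationError(RangeFrameError):
    """One or more rows violate the frame's coordinate-system invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        head = "; ".join(f"row {v.row_id}: {v.reason}" for v in self.violations[:5])
        more = "" if len(self.violations) <= 5 else f" (+{len(self.violations) - 5} more)"
        super().__init__(f"{len(self.violations)} invalid row(s): {head}{more}")


class CoordinateError(RangeFrameError):
    """A coordinate conversion has no valid representation in the target system."""


class ParseError(RangeFrameError):
    """A file could not be parsed; carries the 1-based line number."""

    def __init__(self, path, lineno: int | None, reason: str):
        self.path = str(path)
        self.lineno = lineno
        self.reason = reason
        where = f"{self.path}" if lineno is None else f"{self.path}, line {lineno}"
        super().__init__(f"{where}: {reason}")
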