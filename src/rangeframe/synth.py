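"""Deterministic synthetic interval generation for testing and benchmarking.

The generator emulates the shape of the two dataset families used to
benchmark genomic-interval engines: a synthetic design — intervals of fixed
length dropped uniformly at random on one long chromosome — and
real-data-like shapes where the two join sides differ in cardinality by
roughly an order of magnitude (e.g. 10^7 vs 1.2*10^6 intervals, which
:func:`benchmark_pair` reproduces at any down-scaled size).

Randomness comes from a counter-based splitmix64 mixing function rather than
a platform RNG: every draw is a pure integer function of ``(seed, counter)``,
so a given spec yields byte-identical frames on every platform and run, and
rows are independent of generation order.  The ``fixed`` and ``uniform``
length models use integer arithmetic only; the ``geometric`` model maps the
64-bit draw through IEEE-754 double inversion and is deterministic on any
IEEE-conforming platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .frame import CoordSystem, IntervalFrame

__all__ = ["LengthModel", "GeneratorSpec", "generate", "generate_pair", "benchmark_pair"]

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)

DEFAULT_CONTIGS = (("chr1", 250_000_000),)


def _splitmix64(seed: int, counters: np.ndarray) -> np.ndarray:
    """The splitmix64 output stream at positions ``counters`` for ``seed``."""
    z = _U64(seed & 0xFFFFFFFFFFFFFFFF) + (counters.astype(_U64) + _U64(1)) * _GOLDEN
    z = (z ^ (z >> _U64(30))) * _MIX1
    z = (z ^ (z >> _U64(27))) * _MIX2
    return z ^ (z >> _U64(31))


@dataclass(frozen=True)
class LengthModel:
    """Interval length distribution: ``fixed``, ``uniform`` or ``geometric``."""

    kind: str
    p1: int
    p2: int = 0

    @classmethod
    def fixed(cls, length: int) -> "LengthModel":
        if length < 1:
            raise ValueError("fixed length must be >= 1")
        return cls("fixed", length)

    @classmethod
    def uniform(cls, min_length: int, max_length: int) -> "LengthModel":
        if not 1 <= min_length <= max_length:
            raise ValueError("need 1 <= min_length <= max_length")
        return cls("uniform", min_length, max_length)

    @classmethod
    def geometric(cls, mean_length: int) -> "LengthModel":
        if mean_length < 1:
            raise ValueError("geometric mean length must be >= 1")
        return cls("geometric", mean_length)

    @property
    def max_length(self) -> int:
        if self.kind == "fixed":
            return self.p1
        if self.kind == "uniform":
            return self.p2
        return -1  # unbounded; clipped to the contig

    @property
    def mean(self) -> float:
        if self.kind == "fixed":
            return float(self.p1)
        if self.kind == "uniform":
            return (self.p1 + self.p2) / 2.0
        return float(self.p1)

    def sample(self, draws: np.ndarray) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(len(draws), self.p1, dtype=np.int64)
        if self.kind == "uniform":
            span = _U64(self.p2 - self.p1 + 1)
            return (self.p1 + (draws % span).astype(np.int64)).astype(np.int64)
        if self.kind == "geometric":
            if self.p1 == 1:
                return np.ones(len(draws), dtype=np.int64)
            # inverse-CDF of the geometric distribution on {1, 2, ...}
            u = (draws >> _U64(11)).astype(np.float64) * (2.0 ** -53)
            lengths = 1 + np.floor(np.log1p(-u) / np.log1p(-1.0 / self.p1))
            return np.maximum(lengths.astype(np.int64), 1)
        raise ValueError(f"unknown length model kind: {self.kind!r}")


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic interval frame.

    Defaults reproduce the benchmark-emulation profile: one 250 Mbp contig
    ("chr1"), fixed interval length 1000 bp, uniform random starts.
    """

    n_intervals: int
    contigs: Sequence[tuple[str, int]] = DEFAULT_CONTIGS
    length_model: LengthModel = field(default_factory=lambda: LengthModel.fixed(1000))
    seed: int = 0

    def __post_init__(self):
        if self.n_intervals < 0:
            raise ValueError("n_intervals must be >= 0")
        if not self.contigs:
            raise ValueError("need at least one contig")
        for name, size in self.contigs:
            if size < 1:
                raise ValueError(f"contig {name!r} has non-positive length")
            if self.length_model.max_length > size:
                raise ValueError(
                    f"length model (max {self.length_model.max_length}) exceeds "
                    f"contig {name!r} length {size}"
                )


def generate(spec: GeneratorSpec) -> IntervalFrame:
    """Materialize ``spec`` as a half-open frame with an ``id`` payload column.

    Row ``i`` carries id ``f"f{i}"``; identical specs (including seed) yield
    byte-identical frames.
    """
    n = spec.n_intervals
    idx = np.arange(n, dtype=np.uint64)
    u_contig = _splitmix64(spec.seed, idx * _U64(3))
    u_length = _splitmix64(spec.seed, idx * _U64(3) + _U64(1))
    u_start = _splitmix64(spec.seed, idx * _U64(3) + _U64(2))

    names = np.array([c[0] for c in spec.contigs], dtype=object)
    sizes = np.array([c[1] for c in spec.contigs], dtype=np.int64)
    ci = (u_contig % _U64(len(spec.contigs))).astype(np.int64)
    lengths = np.minimum(spec.length_model.sample(u_length), sizes[ci])
    span = (sizes[ci] - lengths + 1).astype(np.uint64)
    starts = (u_start % span).astype(np.int64)

    df = pd.DataFrame(
        {
            "contig": names[ci] if n else np.array([], dtype=object),
            "start": starts,
            "end": starts + lengths,
            "id": np.char.add("f", np.arange(n).astype(str)) if n else np.array([], dtype=object),
        }
    )
    return IntervalFrame(df, CoordSystem.ZERO_BASED_HALF_OPEN)


def generate_pair(spec_a: GeneratorSpec, spec_b: GeneratorSpec) -> tuple[IntervalFrame, IntervalFrame]:
    """Two independent frames (convenience for benchmark-shaped instances)."""
    return generate(spec_a), generate(spec_b)


def benchmark_pair(
    n_a: int,
    n_b: int | None = None,
    seed: int = 0,
    length: int = 1000,
    contigs: Sequence[tuple[str, int]] = DEFAULT_CONTIGS,
) -> tuple[IntervalFrame, IntervalFrame]:
    """Benchmark-emulation pair: ``n_a`` probe vs ``n_b`` build intervals.

    ``n_b`` defaults to the real-data cardinality ratio (1.2*10^6 per 10^7,
    i.e. ``n_a * 0.12``).  The two sides use decorrelated seed streams
    derived from ``seed``.
    """
    if n_b is None:
        n_b = max(1, int(round(n_a * 0.12)))
    lm = LengthModel.fixed(length)
    sa = GeneratorSpec(n_a, contigs, lm, seed=seed * 2 + 1)
    sb = GeneratorSpec(n_b, contigs, lm, seed=seed * 2 + 2)
    return generate_pair(sa, sb)
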