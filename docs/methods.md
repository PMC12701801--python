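# Methods

`rangeframe` is an in-memory and out-of-core engine for genomic-interval
arithmetic over tabular data. This note documents the model it implements,
the data structure behind it, the numerical and semantic choices that were
genuinely open, and what the synthetic test fixtures do and do not
demonstrate about real data.

## Interval model and coordinate conventions

An interval table (`IntervalFrame`) is a pandas DataFrame with designated
`(contig, start, end)` columns, any number of payload columns, and a
coordinate-convention tag:

* **0-based half-open** `[s, e)` — BED convention. Length is `e − s`;
  `s == e` is a valid zero-length interval (a point between bases).
* **1-based closed** `s..e` — GFF3/VCF convention. Length is `e − s + 1`;
  zero-length spans are unrepresentable.

All operations convert to half-open coordinates on entry and restore the
caller's convention (the probe frame's, for joins) on exit. Half-open was
chosen as the canonical form because intersection, gap, and length
arithmetic need no ±1 corrections and zero-length spans are expressible.
Conversion is the exact map `(s, e)₁-based ↔ (s−1, e)half-open`; round-trips
are bit-identical. Converting a zero-length half-open interval to 1-based
raises rather than silently inventing a span.

Contig names are opaque strings compared by exact equality (`"chr1"` ≠
`"1"`); no alias normalization is attempted, because silent renaming
corrupts joins. Duplicate rows are preserved everywhere: all operations are
multiset-faithful. Coordinates are signed 64-bit integers; negative starts
are rejected at validation (human chromosome 1 alone overflows 32-bit pair
counts in joined outputs).

**Zero-length semantics.** A zero-length interval is treated as a point
`p` that overlaps `[s, e)` iff `s ≤ p < e`; two points overlap iff they
coincide. Internally this is implemented by giving zero-length intervals an
*effective* end of `start + 1` in the overlap predicate only — distances and
covered-base counts always use the true coordinates. Two intervals that
merely touch (`a.end == b.start`) do **not** overlap (no shared base) but
have nearest-distance 0; this asymmetry is deliberate and is asserted in
the tests.

## The four operations

With probe table A (each row drives one query) and build table B (turned
into an index):

* **overlap** — one output row per pair `(aᵢ, bⱼ)` with
  `bⱼ.start < aᵢ.end ∧ aᵢ.start < bⱼ.end` (half-open, same contig);
  `how="left"` additionally keeps unmatched probe rows with null build
  columns.
* **nearest** — for each `aᵢ`, the `k` build rows minimizing
  `d(a, b) = max(0, b.start − a.end, a.start − b.end)`, i.e. the gap in
  bases, 0 for overlapping or touching pairs. Ties break by (build start,
  build end, build row id) — a contract of this package, stated explicitly
  because the field has no consensus tie-break. Every probe row appears;
  probes on contigs absent from B yield one null-match row.
* **count_overlaps** — exactly `|A|` rows in probe order; the number of
  overlapping build rows per probe (duplicates counted).
* **coverage** — exactly `|A|` rows; `covered = |aᵢ ∩ ⋃B|` in base pairs,
  computed against the *merged union* of B so stacked intervals never
  double-count, plus `coverage_fraction = covered / length(aᵢ)` (defined as
  0 for a zero-length probe, avoiding 0/0).

B is always the indexed (build) side and A the streamed (probe) side; the
engine never swaps sides by size. The identity
`Σ count_overlaps(A, B) = |overlap(A, B, inner)|` holds by construction and
is asserted over randomized instances.

## Search structure

Per contig, the index stores intervals sorted by start together with a
running maximum of (effective) end values — an augmented interval list. An
overlap query binary-searches the last start below the query end and scans
backwards; the running maximum bounds how far back any still-overlapping
interval can be, so the scan stops early. On sorted, mostly-disjoint data a
query inspects O(log n + hits) candidates, which an instrumented test
asserts.

Mixtures of many long and short intervals defeat the running-max pruning
(one long interval keeps the maximum high across thousands of short ones).
At build time, intervals that end after at least 16 of the 32 intervals
following them in start order are demoted into a separate component, applied
iteratively up to 8 components with a 64-item minimum; queries visit every
component. The thresholds trade decomposition cost against scan pruning and
are fixed constants, not tuning knobs.

Nearest queries use globally sorted views (by start, and by end) of the same
arrays: distance-0 candidates come from the overlap scan; right-side
candidates (`b.start ≥ q.end`) are read off in ascending start; left-side
candidates (`b.end ≤ q.start`) in descending end. Each side is extended
through ties at its k-th distance so the final (distance, start, end, row)
sort is exact.

The index is immutable; repeated identical queries return identical
results. Table-level queries run through two-pass (count, then fill)
kernels compiled with numba; the same functions execute as plain Python if
numba is unavailable. Coverage needs no per-query scan at all: against the
merged disjoint union, covered bases are a difference of two values of the
step function "union bases below position p", evaluated with vectorized
binary search.

## Streaming execution

Only the build side must fit in memory. The probe side is consumed as
bounded `Batch` objects (default 65,536 rows — large enough to amortize
per-batch overhead, small enough that a batch of typical BED rows stays in
the tens of megabytes); each batch is validated, processed against the
prebuilt index, and its results yielded (and optionally written to a sink)
before the next batch is read. Because every operation in scope is
per-probe-row, streamed output equals eager output as a row multiset — and,
since batches are consecutive row slices, concatenated sorted-per-batch
output equals the sorted eager output exactly. An instrumented counter
verifies the memory contract (peak resident probe rows ≤ batch size) in the
tests. `scan_file` parses BED/GFF3/VCF lazily with the same guarantee on
its parse buffer, and reports malformed lines by number after yielding all
complete batches that precede them.

A batch that violates coordinate invariants aborts the stream with the
row-level violation report; output already emitted is not retracted.

## File formats

Hand-written line-level readers (rather than a generic CSV parser) are used
for BED, GFF3 and VCF because the module's contracts — lazy batched
scanning, per-line error reporting, format-specific header/trailer rules,
and native coordinate tagging — live at the line level. Generic TSV/CSV
input and all tabular output go through pandas.

* **BED**: 3–12 columns; `track`/`browser`/`#` lines skipped; columns 4–6
  named `name`/`score`/`strand`, further columns kept as opaque strings
  (BED12 block semantics are irrelevant to interval arithmetic). Tagged
  half-open.
* **GFF3**: 9 columns, `##` directives skipped, parsing halts at
  `##FASTA`; `.` score/phase become nulls; the attributes column is kept as
  a raw string — attribute schemas are open-ended and unpacking is a
  separate concern. Tagged 1-based closed.
* **VCF**: meta lines and the `#CHROM` header handled, sample columns
  ignored; the record's interval is the REF span
  (`start = POS`, `end = POS + len(REF) − 1`). INFO `END` tags and symbolic
  ALTs are deliberately **not** interpreted: that rule is uniform,
  predictable, and correct for SNVs and indels, but understates the span of
  symbolic structural variants — a documented limitation.
* All readers sniff gzip magic bytes and tolerate CRLF.

## Synthetic data

The generator emulates two benchmark dataset shapes from the interval-join
literature: a synthetic profile (one 250 Mbp contig, fixed 1,000 bp
intervals, uniform random starts — the default) and real-data-like pairs
where the probe side is roughly 8.3× the build side (the 10⁷ vs 1.2×10⁶
cardinality ratio, reproducible at any down-scaled size via
`benchmark_pair`).

Draws come from a counter-based splitmix64 mixing function, fixed forever:
each value is a pure integer function of `(seed, counter)`, so output is
byte-identical across runs, platforms, and generation order. The `fixed`
and `uniform` length models are integer-only; the `geometric` model maps
the 64-bit draw through IEEE-754 double inverse-CDF and is deterministic on
any IEEE-conforming platform. Bounded draws use modulo reduction; the bias
is ≤ 2⁻⁴⁰ for any genomic-scale bound and irrelevant for fixtures.

What the generator does **not** emulate: the clustered, heavy-tailed length
and spacing distributions of real annotation tracks (exons cluster in
genes; repeats tile densely). Passing oracle-equivalence tests on uniform
fixtures demonstrates *correctness* on arbitrary geometries (the randomized
instances include zero-length intervals, duplicates, multiple contigs, and
adversarial long/short mixtures), but performance figures measured on the
uniform profile do not transfer quantitatively to real tracks.

## Validation strategy and problem sizes

Correctness is established against independent brute-force oracles that
share no code with the engine: full pairwise predicate evaluation for
overlap/count/nearest, and a per-base bitmap for coverage and union size.
The main sweep runs 200 seeded instances (≤ 500 intervals per side,
coordinates < 10⁵, 1–3 contigs) per operation; streaming is checked against
eager execution at batch sizes {1, 7, 64, 4096}; a smoke test joins two
generated sets of 10⁶ intervals each, eagerly and streamed, and requires
identical sorted outputs. These sizes keep the full suite around a minute
on one core while covering the regimes (empty sides, single batch, many
batches, million-row scale) where the implementation branches.

## Known limitations

* Strand is carried as payload, never interpreted: no strand-aware or
  reciprocal-overlap joins.
* No bounds checking against an assembly's contig lengths (`.fai` /
  `chrom.sizes`).
* The build side must fit in memory; there is no external-memory index and
  no spill-to-disk.
* Single-threaded by design here; the batch-iterator contract (multiset
  equality + bounded residency) is what a parallel executor would have to
  preserve, and nothing in the API precludes one.
* BAM/FASTA/FASTQ and Parquet are out of scope; inputs are the text interval
  formats above.
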