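# rangeframe

Fast genomic-interval operations on tabular data: **overlap** joins,
**nearest**-feature queries, per-interval **count_overlaps** and
**coverage**, executed against a per-contig augmented interval-list index,
with an out-of-core streaming mode and readers for BED, GFF3 and VCF.

Genomic analyses constantly ask relational questions about features laid
out on a 1-D coordinate axis — which peaks hit which genes, what is the
closest gene to each variant, how many reads fall in each bin, what
fraction of each bin do they cover. `rangeframe` answers these over pandas
DataFrames carrying `(contig, start, end)` plus arbitrary payload columns,
for tables from a handful of rows to millions, without requiring the probe
side of a join to fit in memory.

## The operations

For a probe table A and a build table B (half-open coordinates `[s, e)`;
1-based closed input is converted internally and restored on output):

| operation        | result                                                                 |
|------------------|------------------------------------------------------------------------|
| `overlap(A, B)`  | one row per pair with `b.start < a.end` and `a.start < b.end`          |
| `nearest(A, B)`  | per A row, the k nearest B rows by `d = max(0, b.start−a.end, a.start−b.end)` |
| `count_overlaps(A, B)` | per A row, the number of overlapping B rows                      |
| `coverage(A, B)` | per A row, `|a ∩ ⋃B|` in bases and as a fraction of `len(a)`           |

B is indexed once (sorted starts + running-max ends per contig, decomposed
into sublists when long intervals would defeat the pruning); A is probed
row by row — eagerly, or streamed in bounded batches so only the index and
one batch are ever resident.

## A worked example

```python
import pandas as pd
from rangeframe import IntervalFrame, overlap

peaks = IntervalFrame(pd.DataFrame({
    "contig": ["chr1", "chr1", "chr2"],
    "start":  [100, 500, 50],
    "end":    [200, 650, 80],
    "peak_id": ["p1", "p2", "p3"],
}))
genes = IntervalFrame(pd.DataFrame({
    "contig": ["chr1", "chr1"],
    "start":  [150, 300],
    "end":    [400, 550],
    "gene":   ["geneA", "geneB"],
}))
print(overlap(peaks, genes, how="left").data.to_string(index=False))
```

```
contig_1  start_1  end_1 peak_id_1 contig_2  start_2  end_2 gene_2
    chr1      100    200        p1     chr1      150    400  geneA
    chr1      500    650        p2     chr1      300    550  geneB
    chr2       50     80        p3     <NA>     <NA>   <NA>   <NA>
```

One row per overlapping peak/gene pair — p1 shares bases 150–199 with
geneA, p2 shares 500–549 with geneB — and, because this is a left join, the
chr2 peak p3 is kept with null gene columns. Probe columns carry the `_1`
suffix, build columns `_2`.

The `examples/` directory has one short script per capability: overlap
joins, nearest-feature annotation of a VCF against a gene BED, binned
counts vs. coverage, streaming a large BED through a join with bounded
memory, and coordinate-convention handling.

## Command line

The same operations are available as a thin CLI over the library:

```bash
rangeframe overlap peaks.bed genes.gff3 --sort-output -o hits.tsv
rangeframe nearest variants.vcf genes.bed -k 2 -o nearest.tsv
rangeframe count-overlaps bins.bed reads.bed --streaming -o counts.tsv
rangeframe generate --n 100000 --seed 1 -o synthetic.bed
rangeframe validate suspicious.bed
```

Formats are detected from extensions (`.gz` transparently); results go to
the output path (or stdout with `-o -`), `key=value` diagnostics to stderr.
Exit codes: 0 ok, 1 data error, 2 usage error.

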