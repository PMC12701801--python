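"""Overlap join: which intervals in A share at least one base with B?

Builds two tiny in-memory interval tables and runs the inner and left
variants of the overlap join.
"""

import pandas as pd

from rangeframe import IntervalFrame, overlap

peaks = IntervalFrame(pd.DataFrame({
    "contig": ["chr1", "chr1", "chr2"],
    "start": [100, 500, 50],
    "end": [200, 650, 80],
    "peak_id": ["p1", "p2", "p3"],
}))

genes = IntervalFrame(pd.DataFrame({
    "contig": ["chr1", "chr1"],
    "start": [150, 300],
    "end": [400, 550],
    "gene": ["geneA", "geneB"],
}))

inner = overlap(peaks, genes)
print("inner join (one row per overlapping peak/gene pair):")
print(inner.data.to_string(index=False))
# p1 shares bases 150..199 with geneA; p2 shares 500..549 with geneB.

left = overlap(peaks, genes, how="left")
print("\nleft join (unmatched peaks kept with empty gene columns):")
print(left.data.to_string(index=False))
# p3 is on chr2, where there is no gene, so its gene columns are null.
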