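"""Coordinate conventions: BED's 0-based half-open versus GFF3/VCF's 1-based
closed, and why the engine's answers do not depend on the encoding.

The first base of a chromosome is interval [0, 1) in BED and position 1..1
in GFF3/VCF.  Every frame carries its convention; conversion is explicit and
exactly reversible (except that a zero-length half-open interval has no
1-based closed representation).
"""

import pandas as pd

from rangeframe import CoordSystem, IntervalFrame, convert_coordinates, overlap

half_open = IntervalFrame(
    pd.DataFrame({"contig": ["chr1", "chr1"], "start": [0, 100], "end": [10, 200]}),
    CoordSystem.ZERO_BASED_HALF_OPEN,
)
one_based = convert_coordinates(half_open, CoordSystem.ONE_BASED_CLOSED)

print("half-open (BED-style):")
print(half_open.data.to_string(index=False))
print("\nsame intervals, 1-based closed (GFF3/VCF-style):")
print(one_based.data.to_string(index=False))
# [0, 10) becomes 1..10 — same ten bases, different bookkeeping.

other = IntervalFrame(pd.DataFrame({"contig": ["chr1"], "start": [5], "end": [120]}))
pairs_ho = overlap(half_open, other).n_rows
pairs_ob = overlap(one_based, other).n_rows
print(f"\noverlap pairs from half-open input : {pairs_ho}")
print(f"overlap pairs from 1-based input   : {pairs_ob}")
# Identical: inputs are normalized internally, and the output is expressed
# in whichever convention the probe frame used.
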