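##gff-version 3
chr1	toy	gene	1	100	.	+	.	ID=gene1
chr1	toy	exon	10	50	3.5	+	0	ID=exon1;Parent=gene1
##FASTA
>chr1
ACGTACGT
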