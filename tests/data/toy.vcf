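##fileformat=VCFv4.2
##contig=<ID=chr1>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
chr1	100	rs1	A	G	50	PASS	DP=10
chr1	100	rs2	ACGT	A	.	PASS	SVTYPE=DEL
chr1	200	sv1	T	<DEL>	30	PASS	END=500
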