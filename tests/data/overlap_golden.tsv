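contig_1	start_1	end_1	name_1	contig_2	start_2	end_2	name_2
chr1	0	100	a1	chr1	90	160	b1
chr1	150	250	a2	chr1	90	160	b1
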