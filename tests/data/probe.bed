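chr1	0	100	a1
chr1	150	250	a2
chr2	10	20	a3
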