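chr1	90	160	b1
chr1	300	400	b2
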