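# phobius_short
# name	tm	sp	prediction
p1	0	Y	n8-18c23/24
p2	2	0	i10-32o45-67i
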