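# sp_short
# name	sp	score	cleavage
p1	YES	0.91	23
p2	NO	0.02	-
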