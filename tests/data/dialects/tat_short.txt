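# tat_short
# name	tat	score	cleavage
p1	YES	0.88	30
p2	NO	0.05	-
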