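# lipo_short
# name	class	score	cleavage
p1	SpII	10.94	19
p2	SpI	4.2	24
p3	CYT	-0.2	-
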