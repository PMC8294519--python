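# tm_short
# name	nhelix	topology
p1	2	10-32,45-67
p2	0	-
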