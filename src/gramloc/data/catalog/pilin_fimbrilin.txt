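# Pseudo-pilin and fimbrilin associated signatures.
PF07963	# prokaryotic N-terminal methylation site (type IV pilin)
PS00409	# prokaryotic N-terminal methylation pattern
PF16734	# fimbrial isopeptide-forming D2 family
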