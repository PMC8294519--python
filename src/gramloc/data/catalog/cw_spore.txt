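# Spore coat / spore surface associated signatures.
PF08757	# CotH kinase family spore coat protein
PF05635	# spore coat assembly protein family
TIGR02893	# spore coat protein family
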