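# Covalent cell-wall anchoring (sortase substrates).
PF00746	# Gram-positive anchor (LPXTG)
PS50847	# Gram-positive anchoring profile
TIGR01167	# LPXTG cell wall anchor domain
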