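# Starter list: signatures diagnostic of non-classical secretion routes.
# Optional second column: export route used for "-like" pathway annotation
# (allowed: SecA2, Wss/T7SSb, FEA).
PF06013	Wss/T7SSb	# WXG100 family (ESAT-6-like substrates)
PF10824	Wss/T7SSb	# EsxB-related secreted protein
PF02050	FEA	# flagellar export chaperone FliJ
PF02465	FEA	# flagellar hook-associated family
PF07516	SecA2	# accessory SecA2-dependent substrate family
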