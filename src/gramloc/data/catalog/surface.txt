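# Surface-associated signatures (second-level localization hints).
PF05738	# Cna protein B-type domain (adhesin stalk)
PF02368	# bacterial Ig-like domain, group 2
PF05031	# surface protein repeat family
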