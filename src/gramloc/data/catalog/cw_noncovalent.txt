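# Non-covalent cell-wall binding domains and repeats.
PF01473	# choline-binding repeat (CW_binding_1)
PF04122	# cell wall binding repeat 2
PF01476	# LysM peptidoglycan-binding domain
PF00395	# S-layer homology (SLH) domain
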