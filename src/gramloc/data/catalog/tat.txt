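# Twin-arginine translocation (Tat) associated signatures.
PF10518	# TAT signal domain
PS51318	# TAT signal profile
TIGR01409	# Tat-translocated enzyme RR motif
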