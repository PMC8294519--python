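# Short secreted peptides: lantibiotics, bacteriocins and similar.
PF04604	# type-A lantibiotic
PF10439	# bacteriocin class II family
PF01721	# type-B lantibiotic (mersacidin-like)
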