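# signature_tsv
# name	accession	start	end	score	go_terms
p1	PF00746	160	195	1.2e-30	GO:0005618
p2	PS51257	1	20	.	.
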