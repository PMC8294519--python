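# Lipoprotein-associated signatures (Sec/SpII lipobox).
PS51257	# prokaryotic membrane lipoprotein lipid attachment site
PF08139	# lipoprotein-associated domain
TIGR03434	# conserved lipoprotein family
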