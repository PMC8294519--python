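# GO cellular_component term -> localization tag hint.
GO:0005576	EXTRA	# extracellular region
GO:0005618	CW	# cell wall
GO:0009986	CW	# cell surface
GO:0005737	CYTO	# cytoplasm
GO:0005829	CYTO	# cytosol
GO:0005886	TM	# plasma membrane
GO:0005887	TM	# integral component of plasma membrane
GO:0016020	TM	# membrane
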