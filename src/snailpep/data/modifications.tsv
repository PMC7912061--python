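name	delta_da	applicability
deamidation	0.98402	NQ
oxidation	15.99491	MW
acetylation	42.01057	*
carbamidomethylation	57.02146	C
dehydration	-18.01056	STED
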