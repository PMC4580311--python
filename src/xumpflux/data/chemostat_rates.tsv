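condition	D	q_glucose	q_glycerol	q_methanol	cer	our	biomass_gL	protein_content
glucose	0.1	1.02	0	0	2.11	2.39	28.1	0.40
methanol_glycerol	0.1	0	1.64	0.81	1.86	3.09	31.6	0.54
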