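analyte	bound_methanol_glycerol	bound_glucose	free_methanol_glycerol	free_glucose
Asx	48.8	30.2	5.42	2.91
Ala	32.1	20.2	0.90	1.02
Arg	29.6	25.9	11.1	12.1
Cys	5.59	4.56
Glx	87.0	68.0	22.3	29.4
Gly	18.7	11.5
His	11.9	7.33	0.76	0.74
Ile	17.8	10.6	0.05	0.04
Leu	36.0	22.6	0.10	0.08
Lys	37.5	24.5	0.76	0.92
Met	5.34	4.33	0.04	1.08
Phe	20.0	12.9	0.03	0.03
Pro			0.92	2.76
Ser	25.9	19.0	0.25	0.52
Thr	28.2	19.3	0.24	0.27
Tyr	17.3	8.89	0.06	0.05
Val	26.4	15.7	0.25	0.14
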