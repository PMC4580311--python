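analyte	class	glucose	methanol_glycerol
Glycerophospholipids	phospholipid	8.07	8.92
TG	nonpolar	3.16	1.47
SE	nonpolar	0.22	0.30
Free ergosterol	sterol	1.67	1.83
Free fatty acids	fatty_acid_free	2.11	3.38
C16:0	fatty_acid_total	1.22	1.43
C16:1	fatty_acid_total	0.75	0.85
C18:0	fatty_acid_total	0.33	0.34
C18:1	fatty_acid_total	4.28	3.30
C18:2	fatty_acid_total	3.26	3.45
C18:3	fatty_acid_total	0.96	1.30
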