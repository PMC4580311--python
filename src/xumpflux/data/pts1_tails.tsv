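protein	tail	verdict
AOX1	LGTYEKTGLARF	match
AOX2	LGTYEKTGLARF	match
DAS1	HDLKGKPKHDKL	no
DAS2	TDLKGKPKHDKL	no
DAK2	ITDAYFKSETKL	twilight
FBA1-2	HAAGTFKSESKL	match
FBP1	LTKKIKIQSVNL	no
SHB17	VVPVEEAEADRA	no
RKI1-2	ITSLSVSVPARL	match
TAL1-2	VPSLFRRVLSKL	match
RPE1-2	QKKAKAKPKPNL	twilight
CTA1	QLSPRGDSAARL	match
PMP20	KHSSADRVLAKL	match
FLD	AGNCIRAVITMH	no
FGH1	HAAHHAKYLGLN	no
FDH1	KTKAYGNDKKVA	no
ZWF1	WPVTRPDVLHKM	no
SOL3	ALSGVSVSTSKY	twilight
GND2	KGGNVSASTYDA	no
RPE1-1	QDSLKKKGLLDE	no
RKI1-1	GNEDGSVATLTL	no
TKL1	SPLNKAFESVHA	no
TAL1-1	TLLNLLKEKVQA	no
CIT1	EKYIELVKGLGK	no
ACO1	ALNNMAAVKASK	no
ACO2	INYIGRLKREQQ	no
ICL1	GAGVTEDQFKDH	no
MLS1	LESSPVDLDSLK	no
MDH3	NIAKGTAFIAGN	no
MLS2	STIPINIHQQKL	twilight
AAT1	YLANAIHEVTTN	no
AAT2	RVAAAIDQVVRV	no
ODC1	FTTCMDFFRTLQ	no
OSM1	YLLKSLSNYHKL	twilight
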