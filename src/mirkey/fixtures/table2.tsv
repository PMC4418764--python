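mirna	gene
miR-199-5p	ABL1
miR-199-5p	AKT2
miR-199-5p	APC
miR-199-5p	APPL1
miR-199-5p	BCL2
miR-199-5p	BID
miR-199-5p	CBL
miR-199-5p	CDKN1A
miR-199-5p	CDKN2B
miR-199-5p	CEBPA
miR-199-5p	COL4A4
miR-199-5p	CRKL
miR-199-5p	CYCS
miR-199-5p	E2F2
miR-199-5p	E2F3
miR-199-5p	ERBB2
miR-199-5p	ETS1
miR-199-5p	FGF23
miR-199-5p	FGFR1
miR-199-5p	FZD4
miR-199-5p	FZD5
miR-199-5p	FZD6
miR-199-5p	GLI3
miR-199-5p	GRB2
miR-199-5p	IGF1R
miR-199-5p	ITGA2
miR-199-5p	ITGA6
miR-199-5p	KITLG
miR-199-5p	KRAS
miR-199-5p	LAMB3
miR-199-5p	LAMC1
miR-199-5p	MAPK1
miR-199-5p	MMP2
miR-199-5p	PAX8
miR-199-5p	PIK3R1
miR-199-5p	PIK3R5
miR-199-5p	PML
miR-199-5p	PRKCA
miR-199-5p	PTCH1
miR-199-5p	RARA
miR-199-5p	RUNX1
miR-199-5p	RXRA
miR-199-5p	SMAD2
miR-199-5p	SMAD3
miR-199-5p	STAT1
miR-199-5p	STK4
miR-199-5p	TGFA
miR-199-5p	TGFBR1
miR-199-5p	TPM3
miR-199-5p	TRAF1
miR-199-5p	VEGFA
miR-199-5p	WNT4
miR-199-5p	WNT5A
miR-22	ABL1
miR-22	AKT2
miR-22	AKT3
miR-22	APPL1
miR-22	BCL2L1
miR-22	CBL
miR-22	CDK6
miR-22	CDKN1A
miR-22	CEBPA
miR-22	COL4A4
miR-22	CRK
miR-22	CRKL
miR-22	CYCS
miR-22	E2F2
miR-22	ETS1
miR-22	FAS
miR-22	FGF23
miR-22	FGF5
miR-22	FGFR1
miR-22	FGFR2
miR-22	FGFR3
miR-22	FOXO1
miR-22	FZD5
miR-22	FZD6
miR-22	GLI3
miR-22	GRB2
miR-22	IGF1R
miR-22	LAMC1
miR-22	MAPK1
miR-22	MAPK10
miR-22	MAX
miR-22	PAX8
miR-22	PIK3R5
miR-22	PLD1
miR-22	PML
miR-22	PRKCA
miR-22	PTCH1
miR-22	RET
miR-22	RUNX1
miR-22	RUNX1T1
miR-22	RXRA
miR-22	SMAD3
miR-22	STAT1
miR-22	STK4
miR-22	TCF7
miR-22	TGFBR1
miR-22	TP53
miR-22	TPM3
miR-22	TRAF1
miR-22	TRAF6
miR-22	WNT4
miR-22	WNT5A
miR-22	XIAP
miR-429	AKT2
miR-429	AKT3
miR-429	APPL1
miR-429	BCL2
miR-429	CBL
miR-429	CDC42
miR-429	CDK6
miR-429	CDKN1A
miR-429	CDKN2B
miR-429	CEBPA
miR-429	COL4A4
miR-429	COL4A6
miR-429	CRK
miR-429	CRKL
miR-429	CYCS
miR-429	E2F3
miR-429	ETS1
miR-429	FAS
miR-429	FGF23
miR-429	FN1
miR-429	FOXO1
miR-429	FZD4
miR-429	FZD5
miR-429	FZD6
miR-429	GLI3
miR-429	IGF1
miR-429	ITGA2
miR-429	KITLG
miR-429	KRAS
miR-429	LAMC1
miR-429	MAPK1
miR-429	MITF
miR-429	PIK3R3
miR-429	PLCG1
miR-429	PRKCA
miR-429	PTCH1
miR-429	RAC1
miR-429	RET
miR-429	RUNX1
miR-429	RXRA
miR-429	SMAD2
miR-429	SMAD3
miR-429	SOS1
miR-429	STAT1
miR-429	STK4
miR-429	TGFBR1
miR-429	TRAF6
miR-429	VEGFA
miR-429	WNT4
miR-429	WNT5A
miR-429	XIAP
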