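Arginine transportation	RM	SLC7A1	SLC7A2	SLC7A4
Beta-oxidation	RM	ACAD10	ACAD9	ACADVL	CPT1A	ECH1	ECHS1	HSD17B10	EHHADH
Ceramide synthesis	RM	SPTLC3	SPTLC1	SPTLC2	SPTSSA	KDSR	CERS1	DEGS1	SMPD1	SMPD2	SMPD4	SGMS1	SGMS2	SAMD8
Choline production	RM	SLC44A1	SLC44A2	SLC44A3	CHKA	CHKB	PCYT1A	PCYT1B	CEPT1	CHPT1	AGMO	LYPLA1	LYPLA2	GDPD5	GPCPD1	HSD11B2	HSD17B2	AGPS	AGPAT1	LPIN1	PLA2G4A
Chondroitin sulfate synthesis	RM	XYLT1	XYLT2	B4GALT7	B3GALT6	B3GAT1	B3GAT2	B3GAT3	CSGALNACT1	CSGALNACT2	CHSY3	CHPF	CHSY1	UST	CHST1	CHST2	CHST3	CHST7	CHST11	CHST12	CHST13	CHST15
Circadian rhythm	RM	NPAS2	PER3	PER2	CSNK1D	CRY1	BHLHE41	BHLHE40	NR1D1	CRY2	CSNK1E	PER1	CLOCK	ARNTL
Fatty acid synthesis	RM	FASN	MCAT	RPP14	ACACA	ACACB
Fatty acid transporter	RM	SLC27A1	SLC27A2	SLC27A3	SLC27A4	SLC27A5	SLC27A6	FABP1	FABP2	FABP3	FABP4	FABP5	FABP6	FABP7	FABP9	PMP2
Gluconeogenesis-specific	RM	MDH1	MDH2	PC	PCK1	ENO1	ENO2	ENO3	BPGM	PGAM1	PGAM2	PGK1	PGK2	GAPDH	GAPDHS	ALDOA	ALDOB	ALDOC	FBP1	FBP2	GPI	G6PC	G6PC2	G6PC3	HK1	HK2	HK3	GCK	HKDC1	PFKL	PFKM	PFKP	TPI1	PKLR	PKM
Glutaminolysis	RM	ME1	GOT2	GLS	SLC25A1	MDH2	ACLY	CS	SLC25A11	SLC25A13	OGDH	SDHA	SDHB	SDHC	SDHD	FH
Heparan sulfate synthesis	RM	XYLT1	XYLT2	B4GALT7	B3GALT6	B3GAT1	B3GAT2	B3GAT3	EXTL2	EXTL3	A4GNT	EXT1	EXT2	EXTL1	HS2ST1	GLCE	NDST1	NDST2	NDST3	NDST4	HS3ST1	HS3ST3A1	HS3ST3B1	HS3ST2	HS3ST4	HS3ST5	HS3ST6	HS6ST1	HS6ST2	HS6ST3
Hyaluronic acid synthesis	RM	PGM1	PGM2	UGP2	UGDH	GFPT1	GFPT2	GNPNAT1	PGM3	UAP1	HAS1	HAS2	HAS3
Keratan sulfate synthesis	RM	CHST1
Lysine degradation	RM	AASS	ALDH7A1	AADAT	DHTKD1	GCDH	ECHS1	HADH	HSD17B10	ACAT1	ACAT2
Mevalonate pathway	RM	ACAT1	ACAT2	HMGCS1	HMGCS2	HMGCR	MVK	PMVK	MVD	IDI1	IDI2	GGPS1	FDPS
N-glycosylation complex synthesis phase	RM	MGAT1	MAN2A1	MAN2A2	MGAT2	FUT8	MGAT3	MGAT4A	MGAT4B	MGAT4C	MGAT5	MGAT5B	B4GALT1	ST3GAL3	ST6GAL1
N-glycosylation initial phase	RM	DPAGT1	ALG13	ALG1	ALG2	ALG11	ALG3	DPM1	DPM2	DPM3	ALG9	ALG12	ALG5	ALG6	ALG8	ALG10	OST4	STT3B	STT3A
N-glycosylation processing phase	RM	MOGS	PRKCSH	GANAB	MANEA	MAN1C1	MAN1A2	MAN1B1
O-glycosylation	RM	GALNT1	GALNT10	GALNT11	C1GALT1	ST3GAL1	ST3GAL2	GCNT1	GCNT3	GCNT4	GCNT7	B3GNT3
Phospholipid degradation	RM	PLA2G6	PTGS1	PTGS2	PTGIS	PTGDS	HPGDS	PTGES	PTGES2	PTGES3	TBXAS1	ALOX5	LTA4H	LTC4S	GGT5	GGT3P	DPEP2	DPEP1
Phospholipid synthesis-PA	RM	PGS1	PTPMT1
Phospholipid synthesis-PC	RM	CHKA	CHKB	PCYT1A	PCYT1B	CEPT1	CHPT1
Phospholipid synthesis-PE	RM	ETNK1	ETNK2	CHKB	PCYT2	CEPT1	EPT1
Phospholipid synthesis-PI	RM	CDIPT
Phospholipid synthesis-PS	RM	PTDSS1
Proline synthesis	RM	ALDH18A1	PYCR1	G6PD	PGLS	PGD	PYCR2
Purine dRN de novo synthesis	RM	PPAT	GART	PFAS	PAICS	ADSL	ATIC	IMPDH1	IMPDH2	GMPS	GUK1	NME4	NME1	NME2	NME7	RRM1	RRM2	RRM2B	ADSSL1	ADSS	AK5	AK8	AK3
Purine dRN salvage synthesis	RM	PNP	APRT	ADK	ADA	HPRT1	IMPDH1	IMPDH2	GMPS	GUK1	RRM1	RRM2	RRM2B	NME1	NME2	NME4	NME7	ADSSL1	ADSS	ADSL	AK5	AK8	AK3	DGUOK	DCK
Purine RN de novo synthesis	RM	PPAT	GART	PFAS	PAICS	ADSL	ATIC	IMPDH1	IMPDH2	GMPS	GUK1	NME4	NME1	NME2	NME7	RRM1	RRM2	RRM2B	ADSSL1	ADSS
Purine RN degradation	RM	ADA	PNP	PGM2	RPE	RPIA	TKT	TALDO1
Pyrimidine dRN de novo synthesis	RM	CAD	CMPK1	NME1	NME2	CTPS2	CTPS1
Pyrimidine dRN salvage synthesis	RM	DCK	CDA	TK1	TK2	TYMS	RRM1	RRM2	RRM2B	NME4	NME1	NME2	NME7	DUT	ENPP3	ENPP1	ITPA	DTYMK	NTPCR	CANT1
Pyrimidine RN de novo synthesis	RM	CAD	DHODH	UMPS	CMPK1	CMPK2	NME4	NME1	NME2	NME7	CTPS1	CTPS2
Pyrimidine RN degradation	RM	CDA	UPP2	UPP1	DPYD	DPYS	UPB1
Pyrimidine RN salvage synthesis	RM	CDA	UCK1	UCK2	UCKL1	CMPK1	CMPK2	NME4	NME1	NME2	NME7	CTPS1	CTPS2
Reprogrammed lipid metabolism	RM	ACER1	ACER2	ACER3	CERS1	SGPP1	SGPL1	ACLY	FASN	SCD	FFAR1	FFAR2	FFAR3	FFAR4	GPR84	SLC27A3	HADH	HSD17B10	CPT1A	PPP1R14A	ACSL3	PCCB	DGAT1	DGKA	MOGAT1	LPCAT3	LIPE	PNLIP	LPL	DAGLA	DAGLB	CHKA	PTDSS1	CDIPT	SMPD2	SMPD1	SGMS1	SGMS2	S1PR1	S1PR2	S1PR3	PTGS1	PTGS2	ALOX5	TBXAS1	PTGIS	PTGES	PTGES2	PTGES3	PTGDS	LTA4H	LTC4S	GGT5	GGT3P	DPEP1	DPEP2	SPHK1
Retinol biosynthesis	RM	RDH8	RDH10	RDH12	PNLIP	LIPC	RBP2	RBP1	RBP5	BCO1
Retinol metabolism	RM	RDH16	SDR16C5	ALDH1A2	ALDH1A1	ALDH1A3	XDH	LRAT	CES1	CES2	RBP4	CES5A	CES4A
Serine synthesis	RM	PHGDH	PSAT1	VPS29	PSPH	SLC1A4	SLC1A5
Sialic acid synthesis	RM	GNE	NANS	NANP	CMAS	SLC35A1
Triglyceride degradation	RM	LIPE	PNLIP	DAGLB	DAGLA
Triglyceride synthesis	RM	GPAM	GPAT2	AGPAT1	MBOAT1	MBOAT7	MOGAT3	MOGAT1	DGAT2	DGAT1	LPCAT1	AGPAT6	LPPR3	LPPR4
Tryptophan degradation	RM	TDO2	IDO1	IDO2	AFMID	KMO	KYNU	HAAO	ACMSD	ALDH8A1	DHTKD1	GCDH	ECHS1	HADH	HSD17B10	ACAT1	ACAT2	GOT2	AADAT	CCBL1	CCBL2
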