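mirna_id	mrna_id
hsa-miR-1277-5p	APCS
hsa-miR-1277-5p	LINC01554
hsa-miR-1277-5p	NPPC
hsa-miR-1277-5p	PLN
hsa-miR-1277-5p	PTGER3
hsa-miR-1277-5p	SERTM1
hsa-miR-1277-5p	SPRR2F
hsa-miR-146a-5p	CCR9
hsa-miR-146a-5p	IL36
hsa-miR-146a-5p	IRF5
hsa-miR-146a-5p	NDNF
hsa-miR-146a-5p	S100A12
hsa-miR-146a-5p	TLR9
hsa-miR-146a-5p	TMEM100
hsa-miR-185-5p	VAT1L
hsa-miR-185-5p	UBXN10
hsa-miR-185-5p	UBE2QL1
hsa-miR-185-5p	SSX7
hsa-miR-185-5p	SMARCC2
hsa-miR-185-5p	SLC36A1
hsa-miR-185-5p	SLAMF6
hsa-miR-185-5p	SET
hsa-miR-185-5p	S100A7A
hsa-miR-185-5p	RNASE2
hsa-miR-185-5p	PRR23B
hsa-miR-185-5p	PLN
hsa-miR-185-5p	PLCB2
hsa-miR-185-5p	PIANP
hsa-miR-185-5p	PCDHA10
hsa-miR-185-5p	PABPC1L2A
hsa-miR-185-5p	NKAIN1
hsa-miR-185-5p	LRRC38
hsa-miR-185-5p	LINC01554
hsa-miR-185-5p	KIR3DL3
hsa-miR-185-5p	KCNK9
hsa-miR-185-5p	KCNJ15
hsa-miR-185-5p	HK2
hsa-miR-185-5p	GPR12
hsa-miR-185-5p	FXYD4
hsa-miR-185-5p	ETV3L
hsa-miR-185-5p	DNAH10OS
hsa-miR-185-5p	DMBX1
hsa-miR-185-5p	DLX2
hsa-miR-185-5p	CXCL16
hsa-miR-185-5p	C5AR1
hsa-miR-185-5p	BAK1
hsa-miR-185-5p	ARL5C
hsa-miR-185-5p	ANKRD63
hsa-miR-193a-3p	TP53AIP1
hsa-miR-193a-3p	RHAG
hsa-miR-193a-3p	PLCB2
hsa-miR-193a-3p	PARP15
hsa-miR-193a-3p	NOS1
hsa-miR-193a-3p	NDOR1
hsa-miR-193a-3p	MAGEE1
hsa-miR-193a-3p	MAGEA3/MAGEA6
hsa-miR-193a-3p	KRT33B
hsa-miR-193a-3p	IQCJ
hsa-miR-193a-3p	HTR1A
hsa-miR-193a-3p	GABRP
hsa-miR-193a-3p	CYP2S1
hsa-miR-193a-3p	CRYAA/CRYAA2
hsa-miR-193a-3p	CNTN2
hsa-miR-193a-3p	BAK1
hsa-miR-324-3p	ZDHHC22
hsa-miR-324-3p	TMEM86A
hsa-miR-324-3p	STS
hsa-miR-324-3p	SCGN
hsa-miR-324-3p	RAPGEFL1
hsa-miR-324-3p	RAB44
hsa-miR-324-3p	PTPRU
hsa-miR-324-3p	PTGER3
hsa-miR-324-3p	PRSS55
hsa-miR-324-3p	PRAMEF22
hsa-miR-324-3p	PPP4R4
hsa-miR-324-3p	NKAIN1
hsa-miR-324-3p	IGF2
hsa-miR-324-3p	FKRP
hsa-miR-324-3p	FAM92B
hsa-miR-324-3p	EFNA3
hsa-miR-324-3p	DUSP13
hsa-miR-324-3p	DNAH10OS
hsa-miR-324-3p	DMBX1
hsa-miR-324-3p	CYP2A6
hsa-miR-324-3p	ARL5C
hsa-miR-324-3p	ALDH3B2
hsa-miR-33a-3p	TMEM69
hsa-miR-33a-3p	P2RY8
hsa-miR-33a-3p	HLA-DQB1
hsa-miR-33a-3p	CDKL4
hsa-miR-33a-3p	ASB18
hsa-miR-33a-5p	TTC4
hsa-miR-33a-5p	TMEM86A
hsa-miR-33a-5p	PLN
hsa-miR-33a-5p	GPR88
hsa-miR-370-3p	UBXN10
hsa-miR-370-3p	TSNARE1
hsa-miR-370-3p	TMEM86A
hsa-miR-370-3p	SLAMF6
hsa-miR-370-3p	SDK2
hsa-miR-370-3p	NKAIN1
hsa-miR-370-3p	DNAH10OS
hsa-miR-370-3p	CRYAA/CRYAA2
hsa-miR-370-3p	CHRND
hsa-miR-370-3p	C10orf25
hsa-miR-376b-5p	ZNF772
hsa-miR-376b-5p	ZNF74
hsa-miR-376b-5p	TMEM69
hsa-miR-376b-5p	SERTM1
hsa-miR-376b-5p	SELL
hsa-miR-376b-5p	SCN11A
hsa-miR-376b-5p	RP5_1052I52
hsa-miR-376b-5p	PADI3
hsa-miR-376b-5p	KRTAP26-1
hsa-miR-376b-5p	KIAA0408
hsa-miR-376b-5p	CHRNA4
hsa-miR-376b-5p	CCR1
hsa-miR-376b-5p	C16orf89
hsa-miR-376b-5p	C10orf25
hsa-miR-376b-5p	BTG4
hsa-miR-491-5p	UROC1
hsa-miR-491-5p	UBXN10
hsa-miR-491-5p	TSNARE1
hsa-miR-491-5p	TMEM86A
hsa-miR-491-5p	TMEM69
hsa-miR-491-5p	TLR9
hsa-miR-491-5p	SMYD1
hsa-miR-491-5p	SLC36A1
hsa-miR-491-5p	SLC25A42
hsa-miR-491-5p	SLC22A12
hsa-miR-491-5p	SELL
hsa-miR-491-5p	S100A7A
hsa-miR-491-5p	RAX
hsa-miR-491-5p	RASGRP4
hsa-miR-491-5p	RAB44
hsa-miR-491-5p	PTPRU
hsa-miR-491-5p	PLCB2
hsa-miR-491-5p	PIANP
hsa-miR-491-5p	PCDHGB2
hsa-miR-491-5p	P2RY8
hsa-miR-491-5p	P2RX2
hsa-miR-491-5p	NOS1
hsa-miR-491-5p	NKAIN1
hsa-miR-491-5p	NCALD
hsa-miR-491-5p	KIR3DL3
hsa-miR-491-5p	KCNIP2
hsa-miR-491-5p	IGFL3
hsa-miR-491-5p	IGF2
hsa-miR-491-5p	HLA-DQB1
hsa-miR-491-5p	GLP1R
hsa-miR-491-5p	FKRP
hsa-miR-491-5p	ELF5
hsa-miR-491-5p	EFNA3
hsa-miR-491-5p	CYP2S1
hsa-miR-491-5p	CNTN2
hsa-miR-491-5p	CHAD
hsa-miR-491-5p	CA1
hsa-miR-491-5p	C5AR1
hsa-miR-491-5p	C1orf229
hsa-miR-491-5p	C1orf115
hsa-miR-491-5p	C17orf107
hsa-miR-491-5p	BAK1
hsa-miR-503-5p	TMEM100
hsa-miR-503-5p	TAT
hsa-miR-503-5p	SLC36A1
hsa-miR-503-5p	KLHL26
hsa-miR-503-5p	IGF2
hsa-miR-503-5p	FKRP
hsa-miR-503-5p	FCGR1A
hsa-miR-503-5p	CYP2S1
hsa-miR-503-5p	BAK1
hsa-miR-503-5p	ARL5C
hsa-miR-503-5p	ALDH3B2
hsa-miR-654-5p	VNN3
hsa-miR-654-5p	UBXN10
hsa-miR-654-5p	UBE2QL1
hsa-miR-654-5p	TSNARE1
hsa-miR-654-5p	TRIM55
hsa-miR-654-5p	TMEM86A
hsa-miR-654-5p	SLC25A42
hsa-miR-654-5p	RORC
hsa-miR-654-5p	RGR
hsa-miR-654-5p	PEBP4
hsa-miR-654-5p	PABPC1L2A
hsa-miR-654-5p	OBP2B
hsa-miR-654-5p	MUC12
hsa-miR-654-5p	MMEL1
hsa-miR-654-5p	KIR3DL3
hsa-miR-654-5p	KCNIP2
hsa-miR-654-5p	GPR88
hsa-miR-654-5p	GPR17
hsa-miR-654-5p	GCM1
hsa-miR-654-5p	FXYD4
hsa-miR-654-5p	ETV3L
hsa-miR-654-5p	DUSP13
hsa-miR-654-5p	DRD2
hsa-miR-654-5p	DNAH10OS
hsa-miR-654-5p	DMBX1
hsa-miR-654-5p	CXCL16
hsa-miR-654-5p	CLEC12B
hsa-miR-654-5p	C17orf50
hsa-miR-654-5p	C17orf107
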