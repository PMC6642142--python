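mirna_id	mrna_id
hsa-let-7a-5p	AC144568.2
hsa-let-7a-5p	ARHGEF15
hsa-let-7a-5p	ARHGEF39
hsa-let-7a-5p	ATXN1L
hsa-let-7a-5p	CACNG4
hsa-let-7a-5p	CBL
hsa-let-7a-5p	CCL3L1
hsa-let-7a-5p	CXorf36
hsa-let-7a-5p	DRD3
hsa-let-7a-5p	GJB4
hsa-let-7a-5p	HOXC11
hsa-let-7a-5p	IL12RB2
hsa-let-7a-5p	KCTD21
hsa-let-7a-5p	LIMD2
hsa-let-7a-5p	LOR
hsa-let-7a-5p	LRRC10
hsa-let-7a-5p	MS4A7
hsa-let-7a-5p	MYO5B
hsa-let-7a-5p	PADI4
hsa-let-7a-5p	PRLR
hsa-let-7a-5p	PRR18
hsa-let-7a-5p	SALL4
hsa-let-7a-5p	SCN4B
hsa-let-7a-5p	SCYL3
hsa-let-7a-5p	SLC13A3
hsa-let-7a-5p	SPRED3
hsa-let-7a-5p	TBC1D13
hsa-let-7a-5p	TMPPE
hsa-let-7a-5p	TNFSF9
hsa-let-7a-5p	TRIM67
hsa-let-7a-5p	TTC22
hsa-let-7a-5p	ZBTB8B
hsa-let-7a-5p	ZNF835
hsa-let-7a-5p	ZPLD1
hsa-miR-125b-5p	ALOX5
hsa-miR-125b-5p	ARHGEF39
hsa-miR-125b-5p	CCDC169
hsa-miR-125b-5p	CCR5
hsa-miR-125b-5p	CD69
hsa-miR-125b-5p	CTB_54O99
hsa-miR-125b-5p	GLB1L2
hsa-miR-125b-5p	ITGA7
hsa-miR-125b-5p	KCNJ9
hsa-miR-125b-5p	KCNK10
hsa-miR-125b-5p	KCTD21
hsa-miR-125b-5p	LIMD2
hsa-miR-125b-5p	MALL
hsa-miR-125b-5p	OVOL1
hsa-miR-125b-5p	PLD6
hsa-miR-125b-5p	PRAMEF18/PRAMEF19
hsa-miR-125b-5p	RASD2
hsa-miR-125b-5p	RASGRF2
hsa-miR-125b-5p	SERPINE3
hsa-miR-125b-5p	SHTN1
hsa-miR-125b-5p	SLC25A48
hsa-miR-125b-5p	ST8SIA4
hsa-miR-125b-5p	TTPA
hsa-miR-125b-5p	VTCN1
hsa-miR-125b-5p	ZBTB8B
hsa-miR-130b-5p	CCDC170
hsa-miR-130b-5p	CCSER1
hsa-miR-130b-5p	CEP83
hsa-miR-130b-5p	ENDOU
hsa-miR-130b-5p	KCNJ13
hsa-miR-130b-5p	LHX6
hsa-miR-130b-5p	OR2H1
hsa-miR-130b-5p	RAET1L
hsa-miR-130b-5p	RNF138
hsa-miR-130b-5p	SLC26A4
hsa-miR-130b-5p	SMOC1
hsa-miR-130b-5p	SYN3
hsa-miR-130b-5p	ULBP2
hsa-miR-133a-3p	ARHGEF39
hsa-miR-133a-3p	BMP7
hsa-miR-133a-3p	CACNA2D4
hsa-miR-133a-3p	CELF6
hsa-miR-133a-3p	COL9A2
hsa-miR-133a-3p	DAND5
hsa-miR-133a-3p	DOLPP1
hsa-miR-133a-3p	GLOD5
hsa-miR-133a-3p	GZMM
hsa-miR-133a-3p	KCNJ9
hsa-miR-133a-3p	PIRT
hsa-miR-133a-3p	PROK1
hsa-miR-133a-3p	PRR30
hsa-miR-133a-3p	RASGRF2
hsa-miR-133a-3p	SH3GL2
hsa-miR-133a-3p	SIGLEC8
hsa-miR-133a-3p	SLC7A2
hsa-miR-133a-3p	TDRKH
hsa-miR-133a-3p	ZNF69
hsa-miR-454-3p	CD69
hsa-miR-454-3p	CDK19
hsa-miR-454-3p	ELK3
hsa-miR-454-3p	FAM129C
hsa-miR-454-3p	GRK7
hsa-miR-454-3p	KCNK10
hsa-miR-454-3p	MCHR1
hsa-miR-454-3p	MS4A7
hsa-miR-454-3p	NMUR2
hsa-miR-454-3p	ODF4
hsa-miR-454-3p	PLPPR1
hsa-miR-454-3p	RASGRF2
hsa-miR-454-3p	RD3
hsa-miR-454-3p	RGS7BP
hsa-miR-454-3p	SMOC1
hsa-miR-454-3p	ST8SIA5
hsa-miR-454-3p	ZPLD1
hsa-miR-10b-5p	ANXA13
hsa-miR-10b-5p	AWAT1
hsa-miR-10b-5p	CHST9
hsa-miR-10b-5p	DAND5
hsa-miR-10b-5p	FCMR
hsa-miR-10b-5p	IL5RA
hsa-miR-10b-5p	LHPP
hsa-miR-10b-5p	NPAS3
hsa-miR-10b-5p	PLA1A
hsa-miR-10b-5p	PRAMEF18/PRAMEF19
hsa-miR-10b-5p	SLC6A19
hsa-miR-10b-5p	SLC7A2
hsa-miR-10b-5p	SYNGR1
hsa-miR-10b-5p	ZNF69
hsa-miR-98-3p	AC144568.2
hsa-miR-98-3p	ALG10B
hsa-miR-98-3p	C20orf197
hsa-miR-98-3p	P2RY13
hsa-miR-98-3p	RAD51B
hsa-miR-98-3p	RNF138
hsa-miR-98-3p	SLC25A31
hsa-miR-98-3p	ST8SIA4
hsa-miR-98-3p	ZC2HC1B
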