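hsa04658	Th1 and Th2 cell differentiation	IL2	IL4	IL12A	STAT4	STAT6	HLA-DRB1
hsa04612	Antigen processing and presentation	HLA-A	HLA-B	HLA-DRB1	TAP1	TAP2	PSMB8
hsa04640	Hematopoietic cell lineage	CD34	CD38	IL7R	FLT3	KIT	CSF1R
hsa04659	Th17 cell differentiation	IL17A	IL21	IL23A	RORC	STAT3	IL6
hsa04672	Intestinal immune network for IgA production	TNFSF13	ICOS	CXCR4	AICDA	TGFB1	IL10
hsa04650	Natural killer cell-mediated cytotoxicity	KLRD1	NCR1	PRF1	GZMB	KIR3DL3	FCGR3A
hsa04668	TNF signalling pathway	TNF	TNFRSF1A	TRAF2	NFKB1	MAP3K7	RIPK1
hsa04630	JAK-STAT signalling pathway	JAK1	JAK2	TYK2	STAT1	STAT4	IFNK
hsa04622	RIG-I-like receptor signalling pathway	DDX58	IFIH1	MAVS	IRF3	IRF7	TBK1
hsa04621	NOD-like receptor signalling pathway	NOD2	NLRP3	CASP1	PYCARD	NFKB1	RIPK2
hsa04610	Complement and coagulation cascades	C1QA	C2	C3	C4A	CFB	F2
hsa04620	Toll-like receptor signalling pathway	TLR4	TLR7	TLR9	MYD88	IRAK4	IRF5
hsa04060	Cytokine-cytokine receptor interaction	IL2	IL6	IL10	TNF	IFNG	CXCL10	CCR5
hsa04625	C-type lectin receptor signalling pathway	CLEC7A	CLEC4E	SYK	CARD9	MALT1	BCL10
hsa04657	IL-17 signalling pathway	IL17A	IL17RA	ACT1	TRAF6	NFKB1	CXCL1
hsa04664	Fc epsilon RI signalling pathway	FCER1A	FCER1G	LYN	SYK	PLCG1	VAV1
hsa04061	Viral protein interaction with cytokine and receptor	CCL5	CXCL10	CCR1	CCR5	IL10	TNF
hsa04064	NF-kappa B signalling pathway	NFKB1	RELA	NFKBIA	IKBKB	TRAF6	LTB
hsa04380	Osteoclast differentiation	TNFSF11	TNFRSF11A	CSF1	FOSB	NFATC1	SOCS1
hsa04660	T cell receptor signalling pathway	CD3E	CD4	LCK	ZAP70	LAT	PTPN22
hsa04623	Cytosolic DNA-sensing pathway	CGAS	TMEM173	TBK1	IRF3	AIM2	IFI16
hsa04062	Chemokine signalling pathway	CXCL8	CXCR4	CCL2	CCR2	GNAI2	PIK3CG
hsa04514	Cell adhesion molecules	ICAM1	VCAM1	ITGAL	ITGB2	PECAM1	SELL
hsa04145	Phagosome	FCGR1A	TLR2	TUBB	ATP6V1A	CTSL	NCF2
hsa04142	Lysosome	CTSB	CTSD	LAMP1	LAMP2	GLA	HEXA
hsa04210	Apoptosis	CASP3	CASP8	CASP9	BAX	BCL2	FAS
hsa04217	Necroptosis	RIPK1	RIPK3	MLKL	ZBP1	TNF	FADD
hsa04662	B cell receptor signalling pathway	CD79A	CD79B	BTK	SYK	BLNK	BANK1
hsa04666	Fc gamma R-mediated phagocytosis	FCGR2A	FCGR2B	SYK	PIK3CA	RAC1	WAS
hsa04670	Leukocyte transendothelial migration	ICAM1	PECAM1	CXCR4	ITGB1	MMP9	ACTB
hsa04611	Platelet activation	GP1BA	ITGA2B	ITGB3	F2R	PLCB2	P2RY12
hsa04613	Neutrophil extracellular trap formation	ELANE	MPO	PADI4	HDAC1	TLR4	FCGR3A
hsa04140	Autophagy	ATG5	ATG7	BECN1	MAP1LC3B	ULK1	PIK3C3
hsa04216	Ferroptosis	GPX4	SLC7A11	ACSL4	TFRC	FTH1	NCOA4
hsa04218	Cellular senescence	TP53	CDKN1A	CDKN2A	RB1	E2F1	MDM2
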