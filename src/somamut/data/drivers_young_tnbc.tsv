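sample_id	og	tsg	dual	putative
BB01_044	-	-	BIRC6:?,KMT2D:?,TP53:-	-
BB01_074	BCL9:?,CCND3:?	ATM:?,DICER1:?,LRP1B:?	CREBBP:-,TP53:-	-
BB01_109	ETV1:b	-	TP53:-	-
BB01_126	RET:?	-	TP53:-	-
BR067	ACK3:?,ETV4:?,GRM3:?,MUC4:?	-	STAT5B:?,TP53:-	-
BR078	-	-	-	HERC1,HUWE1
BR080	BRAF:?	NRG1:?	TP53:-	-
BR088	-	-	-	KIF13B
BR091	-	-	TP53:-	-
BR097	NR4A3:?,PIK3CA:++,PTPN11:?	DICER1:--,NF1:-	FOXO3:?,TP53:-	-
BR100	MET:?,PIK3CB:?	KMT2C:?,LRP1B:?	TP53:-	-
BR105	RANBP2:?,UBR5:?	LRP1B:?	TP53:-	-
BR108	MUC16:?	SMARCA4:-	BIRC6:?,TP53:-	-
BR121	AFF3:?,BRAF:?	ATRX:?	-	-
BR145	-	ASXL2:?	TP53:-	-
BR164	UBR5:?	-	TP53:-	-
BR176	ERBB2:?,MUC4:b	CLTCL1:?	TP53:-	-
BR200	PREX2:?,TRRAP:?	LRIG3:?	ELF4:?,TP53:-	-
BR255	CHST11:?,DNM2:?	BARD1:?,ETV6:?,FHIT:?,LPR1B:?,POLG:?,TET2:b	-	-
BR301	MUC4:b	CTLCL1:?	LEF1:?,TP53:-	-
BR313	USP6:b	-	TP53:-	-
BR367	STIL:?	-	TP53:-	-
BR393	-	ZFHX3:?,ZMYM3:?	TET1:?,TP53:-	-
BR395	-	-	TP53:-	-
BR-M-045	CARD11:b,HLF:?,MUC16:?	LRP1B:?	TP53:-	-
BR-V-022	-	CDH1:b,LRP1B:?	TP53:-	-
BR-V-051	-	-	TP53:-	-
BR-V-070	-	-	NOTCH1:?	-
PD11326a	-	AXIN2:b,KAT6B:b	TP53:-	-
PD13627a	-	PTPRC:?	-	-
PD18024a	-	-	TP53:-	-
PD22036a	-	NF1:-	-	-
PD22358a	CDH17:?	POLE:?,SETD2:?	-	-
PD23554a	FLI1:b	BAZ1A:?	KMT2D:?,TP53:-	-
PD23563a	IL6ST:?	SPOP:?	TP53:-	-
PD23566a	HIST1H3B:?,MET:?	PTPRD:-	FES:?,TP53:-	-
PD24182a	MUC4:?,TRIM27:b	CDX2:?,CSMD3:?	TP53:-	-
PD24186a	RAC1:?	-	-	-
PD24191a	CACNA1D:?,MUC16:?,MUC4:?	PTEN:-	-	-
PD24196	-	FAT4:?,PTPN13:b	TP53:-	-
PD24202a	PPM1D:?	NF1:-	FOXO3:?	-
PD24337a	XPO1:?	CDH11:?,PTPRD:?	TP53:-	-
PD3905a	PIK3CA:++	-	TP53:-	-
PD4005a	-	ERCC5:b,PTPN6:?	TBL1XR1:?,TP53:-	-
PD4006a	-	-	-	MYT1,NFKB1
PD4107a	ABL2:b,POU2AF1:?	ARHGEF12:?	NTRK1:?,TP53:-	-
PD4833a	UBR5:?	-	BCL9L:?,TP53:-	-
PD4836a	-	ARID1B:?,LARP4B:?	TP53:-	-
PD5930a	-	PHF6:-	RECQL4:?	-
PD5945a	-	-	NFE2L2:?,TP53:-	-
PD6406a	PREX2:?	-	-	-
PD6411a	PREX2:b	-	TP53:-	-
PD6413a	-	TET2:?	-	-
PD6722a	CSF3R:?	FAZ:?,RB1:-	TP53:-	-
PD9004a	SSX1:b,TNC:b	CDC73:?,DNMT3A:?,GRIN2A:?	TP53:-	-
PD9595a	CSF1R:?	-	BTK:?,TP53:-	-
PD9696a	BCL11A:?	WNK2:?	CUX1:?,TP53:-	-
SA083	-	ZFHX3:-	-	-
SA097	BRD4:?,PRDM16:?	CCDC6:b	TP53:-	-
SA208	-	PIK3R1:-	-	-
SA220	FOXP1:?,NFATC2:?	ATR:?,ROBO2:b,SMARCA4:?	-	-
SA231	-	-	-	MBD2
SA235	-	BAP1:?	-	-
SA236	FLT3:?,MUC16:?	ARID2:?,IGF2BP2:?	TP53:-	-
TCGA-A1-A0SP-01	-	ARID1A:?,ZMYM3:?	TP53:-	-
TCGA-A2-A04P-01	ERBB3:b,GRM3:?,PIK3CA:++,SETDB1:?	ACVR2A:?,BRCA2:?,ROBO2:?,TNFAIP3:?	IRS4:?,TP53:-	-
TCGA-A2-A0CM-01	KAT6A:?	CDH11:?,MGMT:?	-	-
TCGA-A2-A3XU-01	-	-	-	-
TCGA-AO-A124-01	CCR7:?,CSF3R:?,MAP2K2:?,MUC16:?	BRCA2:?,CDKN2A:-,EXT2:?,FANCG:?	TP53:-	-
TCGA-AO-A129-01	BCL11A:?,IL6ST:?,USP6:?	DDX3X:?,KAT6B:?	MAP3K13:?,TP53:-	-
TCGA-AO-A12F-01	-	-	-	TAF1
TCGA-AR-A0TU-01	AKT3:?,ETV1:?	GRIN2A:-,NF2:-	-	-
TCGA-AR-A0U1-01	-	BCOR:?,RSPO2:?	TP53:-	-
TCGA-B6-A0IQ-01	-	SMC1A:?	TP53:-	-
TCGA-B6-A0RS-01	A1CF:?,CHD4:?,MET:?,MUC16:?	MED12:?,MUTYH:?,ZMYM3:?	TP53:-	-
TCGA-B6-A0RT-01	GRM3:?,MUC16:?	-	TP53:-	-
TCGA-B6-A0RU-01	ARHGAP5:?	-	POLQ:?,TP53:-	-
TCGA-B6-A0WX-01	-	SLC34A2:?,ZNRF3:?	EPAS1:b,TP53:-	-
TCGA-BH-A0BL-01	HLF:?	CSMD3:?,LZTR1:-	TP53:-	-
TCGA-BH-A0E0-01	ALK:?	-	NOTCH1:?,RHOA:-,TP53:-	-
TCGA-D8-A27F-01	MDM4:b	BAP1:-,CSMD3:?	BIRC6:?,TP53:-	-
TCGA-E2-A14N-01	MAPK1:?,ROS1:?	ABI1:?,PTCH1:?	TP53:-	-
TCGA-E2-A1L7-01	SGK1:?	GPC5:?,PTPRB:?	TP53:-	-
TCGA-E9-A3QA-01	-	NF1:-,POT1:b	-	-
TCGA-OL-A5RW-01	AFF3:b,CTNND2:?,HNRNPA2B1:?,MUC4:b,RAF1:?	ATM:b,AXIN1:?,CBLB:?,MED12:-	IRS4:?	-
TCGA-OL-A66I-01	RANBP2:?	CYLD:?	TP53:-	-
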