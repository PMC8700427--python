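sample_id	og	tsg	dual	putative
TCGA-04-1331-01	DDIT3:?	BRCA2:-,KDM5C:?,LATS1:?,NF1:?	TBL1XR1:?,TP53:-	-
TCGA-04-1337-01	-	CDH1:?,FBXW7:--	ELF4:?,TP53:-	-
TCGA-04-1338-01	MTOR:?	CDH11:?,FAT1:b,KMT2C:?	CREBBP:-,PABPC1:?,TP53:-	-
TCGA-04-1341-01	CTNND2:?,GRM3:?,PDGFRA:?,PREX2:?,TCF7L2:?	CDH10:?,FANCA:?,ATR:?	TP53:-	-
TCGA-04-1342-01	KIT:?	LZTR1:?,SMARCA4:?	-	-
TCGA-04-1347-01	BRAF:?,GRM3:?	DROSHA:?,FAT1:?	TP53:-	-
TCGA-04-1351-01	-	-	-	-
TCGA-04-1365-01	AFF3:?	ZFHX3:-	TP53:-	-
TCGA-04-1517-01	-	-	TP53:-	-
TCGA-04-1652-01	-	LRP1B:?,PTPRT:?	TP53:-	-
TCGA-09-0364-01	-	CNOT3:?,CNTNAP2:?	TP53:-	-
TCGA-09-1661-01	DDIT3:?	PBMR1:?,TNFAIP3:?	TP53:-	-
TCGA-09-1672-01	KRAS:++	-	-	-
TCGA-09-1674-01	LPP:?,PIK3CB:?	HNF1A:-,PALB2:b,RB1:-,SETD2:?	TP53:-	-
TCGA-09-2044-01	CTNNB1:?,MET:?	PTPN13:?,RMI2:?,TSC1:-	TP53:-	-
TCGA-10-0933-01	MUC16:?	RB1:-	RHOA:?,TP53:-	-
TCGA-10-0938-01	NUP98:?,SND1:?	-	TP53:-	-
TCGA-13-0755-01	MUC16:?	ARID2:?,FEN1:?,GRIN2A:?,KMT2C:?	TP53:-	-
TCGA-13-0802-01	-	-	-	-
TCGA-13-0888-01	CRTC1:?,MYCN:?,RAP1GDS1:?,SOX2:?	BARD1:?,EBF1:?,EP300:?,USP44:?,ZFHX3:?	TP53:-	-
TCGA-13-0889-01	ERBB2:?	AMER1:?,ATRX:?	TP53:-	-
TCGA-13-1411-01	-	CLTCL1:?,DICER1:?,SMARCB1:?	TP53:-	-
TCGA-13-1481-01	ARHGAP5:?,GLI1:?,MUC16:?,RARA:?	BRCA2:-	TP53:-	-
TCGA-13-1507-01	ATF1:?,SETDB1:?	MLH1:?,PTPRT:?	TP53:-	-
TCGA-20-0991-01	MACC1:?	-	TP53:-	-
TCGA-20-1686-01	WAS:?	CSMD3:?,SLC34A2:?	IRS4:?,TP53:-	-
TCGA-23-1116-01	-	-	TP53:-	-
TCGA-23-2641-01	-	-	NOTCH2:?,TP53:-	-
TCGA-24-0966-01	-	LZTR1:?,N4BP2:?	CREBBP:?,TET1:?,TP53:-	-
TCGA-24-0982-01	-	SMC1A:?	TP53:-	-
TCGA-24-1422-01	CHD4:?,MUC16:?	XPC:?	TP53:-	-
TCGA-24-1552-01	-	-	TP53:-	-
TCGA-24-1849-01	BRD4:?	GPC5:?,RB1:-	BTK:?,TP53:-	-
TCGA-24-2030-01	-	NDRG1:?	BIRC6:?,TP53:-	-
TCGA-24-2033-01	AFF4:?,GNAS:?	DNM2:?,STAG1:?	BIRC6:?,CBLC:?,EZH2:?,TP53:-	-
TCGA-24-2261-01	-	CSMD3:?	TP53:-	-
TCGA-25-1325-01	MUC16:?	FAT4:?	TP53:-	-
TCGA-25-1329-01	MTOR:*	-	TP53:-	-
TCGA-25-1634-01	EGFR:?	EIF3E:?	TBX3:-	-
TCGA-25-2392-01	FGFR4:?,SRC:?	CDK12:--,USP44:?	TP53:-	-
TCGA-25-2393-01	-	MED12:?,RNF43:?	BCORL1:?	-
TCGA-25-2399-01	CACNA1D:?	ATM:-,NCOR1:?	TP53:-	-
TCGA-25-2400-01	WAS:?	LPR1B:?	TP53:-	-
TCGA-29-1702-01	KIT:b	SLC34A2:?	TP53:-	-
TCGA-29-1761-01	-	CNTNAP2:?,FANCA:-,PRMD2:b,SMC1A:?	TP53:-	-
TCGA-29-1771-01	KMT2A:?	NF1:-	TP53:-	-
TCGA-29-1774-01	-	DROSHA:?,SIRPA:?	-	-
TCGA-29-1778-01	KMT2A:?	-	TP53:-	-
TCGA-29-2429-01	PSIP1:?,ROS1:?	ATM:?,FLCN:-	-	-
TCGA-31-1950-01	PAX3:?	CCD6:?,CTCTCL1:?	CREBBP:?,TP53:-	-
TCGA-36-1575-01	-	KDM5C:?	TP53:-	-
TCGA-36-1576-01	TSHR:?	-	-	-
TCGA-36-2543-01	RET:b,UBR5:?	NF1:-	TP53:-	-
TCGA-42-2587-01	AFF4:?,FCRL4:?,POU2AF1:?	CDC73:?,WNK2:b	BCL9L:?,ESR1:?,TP53:-	-
TCGA-59-2352-01	A1CF:?,SIX1:?,ZEB1:?	CCDC6:?,CNTNAP2:?,CSMD3:?,PRDM1:?	BIRC6:?,TP53:-	-
TCGA-61-1730-01	ALK:?,PLCG1:?	FAT1:?	TP53:-	-
TCGA-61-1741-01	CHD4:?	-	DAXX:-,TP53:-	-
TCGA-61-1899-01	CDH10:?,PIK3CB:?	CSMD3:?,KMT2C:?	-	-
TCGA-61-2012-01	BCL6:?,SGK1:?	PHF6:-,POLG:?	NOTCH1:?,TBX3:?	-
TCGA-OY-A56Q-01	-	-	TP53:-	-
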