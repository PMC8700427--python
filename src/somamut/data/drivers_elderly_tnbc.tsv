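sample_id	og	tsg	dual	putative
PD10011a	MPL:?	ASXL1:-,KMT2C:-	TP53:-	-
PD13298a	RET:b	CSMD3:?,KMT2C:-,PTPRB:?	NOTCH2:?,TP53:-	-
PD24333a	BRAF:++,KRAS:++,MUC16:?,PDGFRA:?,PIK3CA:++,ROS1:?	KMT2C:-	RAD21:?	-
PD6047a	-	KMT2C:?	TP53:-	-
PD7067a	FLI1:?,TAL1:?	ATM:?,BRCA1:-	POLQ:?,TP53:-	-
PD8982a	CALR:?,MUC16:?,TRRAP:?	ARID1B:?,CDH10:?,CLTC:?,MED12:?,SPEN:?	BIRC6:?,MAP3K1:-,NOTCH1:?,POLQ:?,TP53:-	-
PD9575a	BCL3:?,ERBB3:+	PTEN:-,PTPN13:?	TP53:-	-
PD9584a	H3F3A:?,HRAS:++	-	TBX3:-	-
SA031	BRAF:?,MET:?,NRAS:?	DDX3X:?,STAG2:?	BCORL1:b	-
SA052	-	ATM:-	KDM6A:-,NOTCH1:-	-
SA056	ARGHAP5:?,ERBB4:?,PIK3CA:++	-	TP53:-	-
SA106	FCRL4:b,HIF1A:b	BRCA2:-,CAMTA1:b,CSMD3:?,FLCN:?,SPEN:?	BCL9L:?,TP53:-	-
TCGA-A2-A1G1-01	-	-	CREBBP:-,TP53:-,MAP3K1:?	-
TCGA-AC-A2BK-01	-	MYH9:?,PTPRD:?	KMT2D:-,TP53:-	-
TCGA-AR-A1AJ-01	-	PTEN:--	TP53:-	-
TCGA-BH-A0WA-01	IL6ST:?	AXIN1:?,BRCA1:-	TP53:-	-
TCGA-BH-A18G-01	ARHGAP5:?,BCL9:?,ERBB3:?,MAML2:?,MUC16:?,MUC4:b,TRIM27:?,ZEB1:b	ARHGAP26:?,ARHGEF10L:?,ARID1B:-,ASXL2:?,ATM:-,ATRX:?,BCOR:b,CARS:?,CCNB1IP1:?,CDH10:?,CLTCL1:?,CNOT3:b,CYLD:?,DICER1:?,EP300:?,ERCC3:?,ERCC5:?,ETV6:?,IGH2BP2:?,KDM5C:?,KMT2C:?,MLF1:?,MYH9:?,PPP2R1A:-,TET2:b,ZFHX3:?	FES:?,KDM6A:?,KMT2D:?,MAP3K1:?,QKI:?	-
TCGA-BH-A1F0-01	SGK1:?,STAT3:?	ASXL2:?,GPC5:?,KMT2C:?	-	-
TCGA-BH-A1FC-01	CTNNA2:?,DDX5:?,TCF7L2:?,TEC:?	CLTC:?,NCOR1:?	TP53:-	-
TCGA-C8-A12K-01	-	ATP2B3:?,IKZF1:?,STK11:?	FES:?,IRS4:?,TP53:-	-
TCGA-C8-A131-01	KRAS:++,PIK3CA:++	NTHL1:?,PTPRD:?,SETD2:?	TP53:-	-
TCGA-D8-A1JK-01	CTNNA2:?,KATA:?,PIK3CA:++,STAT3:+,TNC:?	ASXL1:?,FANCD2:?,FAT4:?,NCOR1:?	TP53:-	-
TCGA-E2-A1LK-01	CACNA1D:?	EP300:?,LARP4B:?,MED12:?	KDM6A:-,TP53:-	-
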