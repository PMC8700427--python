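sample_id	og	tsg	dual	putative
TCGA-09-1664-01	KRAS:++	NF1:-	-	-
TCGA-13-0792-01	CTNND2:?	CIITA:?	TP53:-	-
TCGA-13-0793-01	MECOM:?	BAZ1A:?	TP53:-,DAXX:-	-
TCGA-13-0884-01	ACVR1:?,TRRAP:?	CSMD3:?,SLC34A2:?	BIRC3:*,TP53:-	-
TCGA-24-1105-01	-	-	TP53:-	-
TCGA-24-1416-01	PIK3CA:++	-	TP53:-	-
TCGA-25-1328-01	-	-	-	-
TCGA-25-2404-01	-	ZMYM3:?	TP53:-	-
TCGA-25-2408-01	-	CDKN1B:?	-	-
TCGA-29-1688-01	HIP1:b	-	TP53:-	-
TCGA-29-1769-01	SETDB1:?	-	RAD21:?	-
TCGA-29-2436-01	-	KAT6B:?	-	-
TCGA-36-2530-01	ERBB2:?	DNMT3A:?,IKBK:b	-	-
TCGA-36-2537-01	-	-	TP53:-	-
TCGA-36-2538-01	-	ERCC3:?,RB1:-	TP53:-	-
TCGA-36-2540-01	-	-	-	-
TCGA-59-2363-01	-	CLTCL1:?,CSMD3:?,NF1:-	TP53:-	-
TCGA-61-1725-01	JAK3:?	RAD17:?	TP53:-	-
TCGA-61-2008-01	-	BLM:?,CNTNAP2:?	TP53:-	-
TCGA-61-2109-01	CHD4:?	FAT1:?	TP53:-	-
TCGA-61-2611-02	ACKR3:?	-	TP53:-	-
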