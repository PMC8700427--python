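symbol	tier	role
A1CF	1	oncogene
ABI1	1	tsg
ABL2	1	oncogene
ACK3	1	oncogene
ACKR3	1	oncogene
ACVR1	1	oncogene
ACVR2A	1	tsg
AFF3	1	oncogene
AFF4	1	oncogene
AKT3	1	oncogene
ALK	1	oncogene
AMER1	1	tsg
ARGHAP5	1	oncogene
ARHGAP26	1	tsg
ARHGAP5	1	oncogene
ARHGEF10L	1	tsg
ARHGEF12	1	tsg
ARID1A	1	tsg
ARID1B	1	tsg
ARID2	1	tsg
ASXL1	1	tsg
ASXL2	1	tsg
ATF1	1	oncogene
ATM	1	tsg
ATP2B3	1	tsg
ATR	1	tsg
ATRX	1	tsg
AXIN1	1	tsg
AXIN2	1	tsg
BAP1	1	tsg
BARD1	1	tsg
BAZ1A	1	tsg
BCL11A	1	oncogene
BCL3	1	oncogene
BCL6	1	oncogene
BCL9	1	oncogene
BCL9L	1	oncogene/TSG
BCOR	1	tsg
BCORL1	1	oncogene/TSG
BIRC3	1	oncogene/TSG
BIRC6	1	oncogene/TSG
BLM	1	tsg
BRAF	1	oncogene
BRCA1	1	tsg
BRCA2	1	tsg
BRD4	1	oncogene
BTK	1	oncogene/TSG
CACNA1D	1	oncogene
CALR	1	oncogene
CAMTA1	1	tsg
CARD11	1	oncogene
CARS	1	tsg
CBLB	1	tsg
CBLC	1	oncogene/TSG
CCD6	1	tsg
CCDC6	1	tsg
CCNB1IP1	1	tsg
CCND3	1	oncogene
CCR7	1	oncogene
CDC73	1	tsg
CDH1	1	tsg
CDH10	1	oncogene/TSG
CDH11	1	tsg
CDH17	1	oncogene
CDK12	1	tsg
CDKN1B	1	tsg
CDKN2A	1	tsg
CDX2	1	tsg
CHD4	1	oncogene
CHST11	1	oncogene
CIITA	1	tsg
CLTC	1	tsg
CLTCL1	1	tsg
CNOT3	1	tsg
CNTNAP2	1	tsg
CREBBP	1	oncogene/TSG
CRTC1	1	oncogene
CSF1R	1	oncogene
CSF3R	1	oncogene
CSMD3	1	tsg
CTCTCL1	1	tsg
CTLCL1	1	tsg
CTNNA2	1	oncogene
CTNNB1	1	oncogene
CTNND2	1	oncogene
CUX1	1	oncogene/TSG
CYLD	1	tsg
DAXX	1	oncogene/TSG
DDIT3	1	oncogene
DDX3X	1	tsg
DDX5	1	oncogene
DICER1	1	tsg
DNM2	1	oncogene/TSG
DNMT3A	1	tsg
DROSHA	1	tsg
EBF1	1	tsg
EGFR	1	oncogene
EIF3E	1	tsg
ELF4	1	oncogene/TSG
EP300	1	tsg
EPAS1	1	oncogene/TSG
ERBB2	1	oncogene
ERBB3	1	oncogene
ERBB4	1	oncogene
ERCC3	1	tsg
ERCC5	1	tsg
ESR1	1	oncogene/TSG
ETV1	1	oncogene
ETV4	1	oncogene
ETV6	1	tsg
EXT2	1	tsg
EZH2	1	oncogene/TSG
FANCA	1	tsg
FANCD2	1	tsg
FANCG	1	tsg
FAT1	1	tsg
FAT4	1	tsg
FAZ	1	tsg
FBXW7	1	tsg
FCRL4	1	oncogene
FEN1	1	tsg
FES	1	oncogene/TSG
FGFR4	1	oncogene
FHIT	1	tsg
FLCN	1	tsg
FLI1	1	oncogene
FLT3	1	oncogene
FOXO3	1	oncogene/TSG
FOXP1	1	oncogene
GLI1	1	oncogene
GNAS	1	oncogene
GPC5	1	tsg
GRIN2A	1	tsg
GRM3	1	oncogene
H3F3A	1	oncogene
HIF1A	1	oncogene
HIP1	1	oncogene
HIST1H3B	1	oncogene
HLF	1	oncogene
HNF1A	1	tsg
HNRNPA2B1	1	oncogene
HRAS	1	oncogene
IGF2BP2	1	tsg
IGH2BP2	1	tsg
IKBK	1	tsg
IKZF1	1	tsg
IL6ST	1	oncogene
IRS4	1	oncogene/TSG
JAK3	1	oncogene
KAT6A	1	oncogene
KAT6B	1	tsg
KATA	1	oncogene
KDM5C	1	tsg
KDM6A	1	oncogene/TSG
KIT	1	oncogene
KMT2A	1	oncogene
KMT2C	1	tsg
KMT2D	1	oncogene/TSG
KRAS	1	oncogene
LARP4B	1	tsg
LATS1	1	tsg
LEF1	1	oncogene/TSG
LPP	1	oncogene
LPR1B	1	tsg
LRIG3	1	tsg
LRP1B	1	tsg
LZTR1	1	tsg
MACC1	1	oncogene
MAML2	1	oncogene
MAP2K2	1	oncogene
MAP3K1	1	oncogene/TSG
MAP3K13	1	oncogene/TSG
MAPK1	1	oncogene
MDM4	1	oncogene
MECOM	1	oncogene
MED12	1	tsg
MET	1	oncogene
MGMT	1	tsg
MLF1	1	tsg
MLH1	1	tsg
MPL	1	oncogene
MTOR	1	oncogene
MUC16	2	oncogene
MUC4	1	oncogene
MUTYH	1	tsg
MYCN	1	oncogene
MYH9	1	tsg
N4BP2	1	tsg
NCOR1	1	tsg
NDRG1	1	tsg
NF1	1	tsg
NF2	1	tsg
NFATC2	1	oncogene
NFE2L2	1	oncogene/TSG
NOTCH1	1	oncogene/TSG
NOTCH2	1	oncogene/TSG
NR4A3	1	oncogene
NRAS	1	oncogene
NRG1	1	tsg
NTHL1	1	tsg
NTRK1	1	oncogene/TSG
NUP98	1	oncogene
PABPC1	1	oncogene/TSG
PALB2	1	tsg
PAX3	1	oncogene
PBMR1	1	tsg
PDGFRA	1	oncogene
PHF6	1	tsg
PIK3CA	1	oncogene
PIK3CB	1	oncogene
PIK3R1	1	tsg
PLCG1	1	oncogene
POLE	1	tsg
POLG	1	tsg
POLQ	1	oncogene/TSG
POT1	1	tsg
POU2AF1	1	oncogene
PPM1D	1	oncogene
PPP2R1A	1	tsg
PRDM1	1	tsg
PRDM16	1	oncogene
PREX2	1	oncogene
PRMD2	1	tsg
PSIP1	1	oncogene
PTCH1	1	tsg
PTEN	1	tsg
PTPN11	1	oncogene
PTPN13	1	tsg
PTPN6	1	tsg
PTPRB	1	tsg
PTPRC	1	tsg
PTPRD	1	tsg
PTPRT	1	tsg
QKI	1	oncogene/TSG
RAC1	1	oncogene
RAD17	1	tsg
RAD21	1	oncogene/TSG
RAF1	1	oncogene
RANBP2	1	oncogene
RAP1GDS1	1	oncogene
RARA	1	oncogene
RB1	1	tsg
RECQL4	1	oncogene/TSG
RET	1	oncogene
RHOA	1	oncogene/TSG
RMI2	1	tsg
RNF43	1	tsg
ROBO2	1	tsg
ROS1	1	oncogene
RSPO2	1	tsg
SETD2	1	tsg
SETDB1	1	oncogene
SGK1	1	oncogene
SIRPA	1	tsg
SIX1	1	oncogene
SLC34A2	1	tsg
SMARCA4	1	tsg
SMARCB1	1	tsg
SMC1A	1	tsg
SND1	1	oncogene
SOX2	1	oncogene
SPEN	1	tsg
SPOP	1	tsg
SRC	1	oncogene
SSX1	1	oncogene
STAG1	1	tsg
STAG2	1	tsg
STAT3	1	oncogene
STAT5B	1	oncogene/TSG
STIL	1	oncogene
STK11	1	tsg
TAL1	1	oncogene
TBL1XR1	1	oncogene/TSG
TBX3	1	oncogene/TSG
TCF7L2	1	oncogene
TEC	1	oncogene
TET1	1	oncogene/TSG
TET2	1	tsg
TNC	1	oncogene
TNFAIP3	1	tsg
TP53	1	oncogene/TSG
TRIM27	1	oncogene
TRRAP	1	oncogene
TSC1	1	tsg
TSHR	1	oncogene
UBR5	1	oncogene
USP44	1	tsg
USP6	1	oncogene
WAS	1	oncogene
WNK2	1	tsg
XPC	1	tsg
XPO1	1	oncogene
ZEB1	1	oncogene
ZFHX3	1	tsg
ZMYM3	1	tsg
ZNRF3	1	tsg
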