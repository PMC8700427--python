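symbol	pathway
ATM	HRR
ATR	checkpoint
BAP1	HRR
BARD1	HRR
BLM	HRR
BRCA1	HRR
BRCA2	HRR
CDK12	HRR
CENPE	other
CLK2	other
DDB1	NER
ERCC3	NER
ERCC5	NER
FANCA	HRR
FANCD2	HRR
FANCG	HRR
FEN1	BER
HELQ	HRR
HLTF	TLS
MGMT	direct
MLH1	MMR
MSH2	MMR
MSH6	MMR
MUTYH	BER
NTHL1	BER
PALB2	HRR
PMS1	MMR
PMS2	MMR
POLE	polymerase
POLG	polymerase
POLQ	TLS
RAD17	checkpoint
RAD21	other
RAD23B	NER
RAD50	HRR
RAD51	HRR
RAD54B	HRR
RECQL4	HRR
RFC1	replication
TOPBP1	checkpoint
TP53	checkpoint
XPC	NER
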