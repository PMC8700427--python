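symbol
ABL2
AFF3
ATM
AXIN2
BCOR
BCORL1
CAMTA1
CARD11
CCDC6
CDH1
CNOT3
EPAS1
ERBB3
ERCC5
ETV1
FCRL4
FLI1
HIF1A
KAT6B
MDM4
MUC4
POT1
PREX2
PTPN13
RET
ROBO2
SSX1
TET2
TNC
TRIM27
USP6
ZEB1
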