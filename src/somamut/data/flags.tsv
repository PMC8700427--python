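symbol
TTN
MUC16
OBSCN
AHNAK2
SYNE1
FLG
MUC5B
DNAH17
PLEC
DST
SYNE2
NEB
HSPG2
LAMA5
AHNAK
HMCN1
USH2A
DNAH11
MACF1
MUC17
DNAH5
GPR98
FAT1
PKD1
MDN1
RNF213
RYR1
RYR2
RYR3
DNAH2
DNAH3
DNAH8
HYDIN
LRP2
FCGBP
APOB
CSMD3
DNAH7
PCLO
LRP1B
FAT4
VPS13B
ZFHX4
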