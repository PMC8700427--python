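symbol	rank
HERC1	A
HUWE1	A
KIF13B	A
MYT1	A
NFKB1	A
MBD2	A
TAF1	A
ARID4A	A
TRIP12	A
USP9X	A
AKAP9	B
DOCK1	B
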