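symbol
FAT1
HIP1
IKBK
KIT
PALB2
PRMD2
RET
WNK2
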