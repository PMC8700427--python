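symbol
AKT3
BRAF
HRAS
KRAS
MAP2K2
MAPK1
MTOR
NF1
NF2
NRAS
PIK3CA
PIK3CB
PIK3R1
PTEN
RAC1
RAF1
RANBP2
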