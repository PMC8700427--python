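symbol	protein_change	effect
KRAS	p.G12V	gain_of_function
TP53	p.R175H	likely_loss_of_function
TP53	p.R248W	likely_loss_of_function
TP53	p.R213*	likely_loss_of_function
BRAF	p.V600E	gain_of_function
TP53		likely_loss_of_function
KRAS		gain_of_function
HRAS		gain_of_function
PIK3CA		gain_of_function
ERBB3		likely_gain_of_function
PTEN		loss_of_function
NF1		likely_loss_of_function
NF2		likely_loss_of_function
RB1		likely_loss_of_function
BRCA1		likely_loss_of_function
BRCA2		likely_loss_of_function
KMT2C		likely_loss_of_function
ATM		likely_loss_of_function
PHF6		likely_loss_of_function
ZFHX3		likely_loss_of_function
PIK3R1		likely_loss_of_function
GRIN2A		likely_loss_of_function
MED12		likely_loss_of_function
TBX3		likely_loss_of_function
FLCN		likely_loss_of_function
DICER1		loss_of_function
CDK12		loss_of_function
FBXW7		loss_of_function
SMARCA4		likely_loss_of_function
CREBBP		likely_loss_of_function
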