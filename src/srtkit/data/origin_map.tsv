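cancer_type	origin_tissue
ACC	adrenal_gland
BLCA	bladder
LAML	blood
LGG	brain
GBM	brain
BRCA	breast
CESC	cervix
COAD	colon
ESCA	esophagus
KIRP	kidney
KIRC	kidney
KICH	kidney
LIHC	liver
LUAD	lung
LUSC	lung
PCPG	nerve
OV	ovary
PAAD	pancreas
PRAD	prostate
SKCM	skin
STAD	stomach
TGCT	testis
THCA	thyroid
UCS	uterus
UCEC	uterus
CHOL	.
SARC	.
DLBC	.
HNSC	.
MESO	.
READ	.
THYM	.
UVM	.
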