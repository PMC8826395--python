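category	protein
vertical_ribosomal	uS2
vertical_ribosomal	uS3
vertical_ribosomal	uS4
vertical_ribosomal	uS5
vertical_ribosomal	uS7
vertical_ribosomal	uS8
vertical_ribosomal	uS9
vertical_ribosomal	uS10
vertical_ribosomal	uS11
vertical_ribosomal	uS12
vertical_ribosomal	uS13
vertical_ribosomal	uS17
vertical_ribosomal	uS19
vertical_ribosomal	uL1
vertical_ribosomal	uL2
vertical_ribosomal	uL3
vertical_ribosomal	uL4
vertical_ribosomal	uL5
vertical_ribosomal	uL6
vertical_ribosomal	uL11
vertical_ribosomal	uL13
vertical_ribosomal	uL14
vertical_ribosomal	uL15
vertical_ribosomal	uL22
vertical_ribosomal	uL23
vertical_ribosomal	uL24
egt_candidate	OTC
egt_candidate	ASS1
egt_candidate	ARLY
egt_candidate	CPS1
egt_candidate	PGK
egt_candidate	ENO
egt_candidate	GAPDH
egt_candidate	PK
egt_candidate	NAXE
egt_candidate	G6PD
egt_candidate	RPIA
egt_candidate	FUMH
egt_candidate	SDHB
egt_candidate	SDHA
egt_candidate	CS
egt_candidate	MDHM
egt_candidate	DLAT
egt_candidate	DLDH
egt_candidate	ACLY
mito_encoded	MT-ATP6
mito_encoded	MT-CO1
mito_encoded	MT-CO2
mito_encoded	MT-CO3
mito_encoded	MT-CYB
mito_encoded	MT-1
mito_encoded	MT-2
mito_encoded	MT-3
mito_encoded	MT-4
mito_encoded	MT-5
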