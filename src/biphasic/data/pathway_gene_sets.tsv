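# Curated canonical signaling pathway gene sets (p53, PI3K/AKT/mTOR, Wnt, Notch)
# after the Sanchez-Vega et al. pan-cancer pathway templates; user-replaceable.
pathway	gene
p53	TP53
p53	MDM2
p53	MDM4
p53	ATM
p53	CHEK2
p53	RPS6KA3
p53	CDKN2A
PI3K	PIK3CA
PI3K	PIK3CB
PI3K	PIK3R1
PI3K	PIK3R2
PI3K	PIK3R3
PI3K	PTEN
PI3K	INPP4B
PI3K	AKT1
PI3K	AKT2
PI3K	AKT3
PI3K	STK11
PI3K	TSC1
PI3K	TSC2
PI3K	MTOR
PI3K	RICTOR
PI3K	RPTOR
PI3K	RHEB
PI3K	PPP2R1A
Wnt	APC
Wnt	CTNNB1
Wnt	AXIN1
Wnt	AXIN2
Wnt	AMER1
Wnt	RNF43
Wnt	ZNRF3
Wnt	TCF7
Wnt	TCF7L1
Wnt	TCF7L2
Wnt	LEF1
Wnt	FBXW7
Wnt	FAT1
Wnt	ARID1A
Wnt	MYC
Wnt	DKK1
Wnt	DKK2
Wnt	DKK3
Wnt	DKK4
Wnt	LRP5
Wnt	LRP6
Wnt	FZD1
Wnt	FZD2
Wnt	FZD3
Wnt	FZD4
Wnt	FZD5
Wnt	FZD6
Wnt	FZD7
Wnt	FZD8
Wnt	WNT1
Wnt	WNT2
Wnt	WNT3
Wnt	WNT3A
Wnt	WNT4
Wnt	WNT5A
Wnt	WNT5B
Wnt	WNT7A
Wnt	WNT7B
Wnt	WNT10A
Wnt	WNT10B
Wnt	WNT11
Wnt	WNT16
Wnt	GSK3B
Wnt	WIF1
Wnt	SFRP1
Wnt	SFRP2
Wnt	SFRP4
Wnt	SFRP5
Notch	NOTCH1
Notch	NOTCH2
Notch	NOTCH3
Notch	NOTCH4
Notch	HEY1
Notch	HEY2
Notch	HEYL
Notch	HES1
Notch	HES2
Notch	HES3
Notch	HES4
Notch	HES5
Notch	DLL1
Notch	DLL3
Notch	DLL4
Notch	JAG1
Notch	JAG2
Notch	DNER
Notch	EP300
Notch	CREBBP
Notch	CUL1
Notch	FBXW7
Notch	MAML1
Notch	MAML2
Notch	MAML3
Notch	NCOR1
Notch	NCOR2
Notch	KDM5A
Notch	NRARP
Notch	PSEN2
Notch	LFNG
Notch	RFNG
Notch	MFNG
Notch	NCSTN
Notch	APH1A
Notch	SPEN
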