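	A	B	C	D	E	F	G	H
A		AB	/	AD	AE	AF	AG	AH
B	BA		BC	BD	BE	BF	BG	BH
C	CA	CB		CD	CE	CF	CG	CH
D	DA	DB	DC		DE	DF	DG	DH
E	EA	EB	EC	ED		EF	EG	EH
F	FA	FB	FC	FD	FE		/	FH
G	/	GB	GC	GD	GE	GF		GH
H	HA	HB	HC	HD	HE	HF	HG	
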