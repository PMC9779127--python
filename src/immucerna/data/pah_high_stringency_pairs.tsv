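lncrna	mrna	r
JPX	RABEP1	0.952570119
MALAT1	CHUK	0.946039227
SND1-IT1	RXRB	−0.943270822
MALAT1	MAPK3	−0.937237966
SND1-IT1	MAPK3	−0.933509908
MALAT1	TBK1	0.932978885
JPX	ICAM2	−0.931467245
MALAT1	TNFRSF14	−0.931453188
JPX	IREB2	0.92261343
JPX	GDF10	−0.921912199
SND1-IT1	CTF1	−0.921173014
SND1-IT1	ECD	0.920122958
SND1-IT1	HSPA5	0.920074041
MALAT1	NR2F1	−0.919527008
MALAT1	TANK	0.916072818
MALAT1	CTF1	−0.91363069
MALAT1	ECD	0.913586674
MALAT1	CMTM8	−0.910914511
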