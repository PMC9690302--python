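gene	location	partition	group
psbA	all	CBRY2, JPL, SMP, TW, CBTY2|CBTY1	ELSE
psaI	all	TW, CBTY2|JPL, CBRY2, CBTY1, SMP	ELSE
petL	all	TW, CBTY2|JPL, CBRY2, CBTY1, SMP	ELSE
chlN	all	CBTY1|TW, CBTY2, JPL, CBRY2, SMP	ELSE
psbD	all	JPL, SMP|TW, CBTY2, CBRY2, CBTY1	CZ
rpoA	all	JPL, SMP|TW, CBTY2, CBRY2, CBTY1	CZ
ycf2	hinterland	CBRY2|JPL, SMP|CBTY2, CBTY1	CZ
cemA	all	TW|JPL, CBTY2, CBRY2, CBTY1, SMP	TW
rpl16	all	TW|JPL, CBTY2, CBRY2, CBTY1, SMP	TW
chlB	all	TW|JPL, CBTY2, CBRY2, CBTY1, SMP	TW
pafI	all	TW|JPL, CBTY2, CBRY2, CBTY1, SMP	TW
psbK	all	TW|JPL, CBTY2, CBRY2, CBTY1, SMP	TW
matK	all	TW|JPL, CBTY2, CBRY2, CBTY1, SMP	TW
rpl2	all	TW|JPL, CBTY2, CBRY2, CBTY1, SMP	TW
atpF	all	TW|JPL, CBTY2, CBRY2, CBTY1, SMP	TW
petB	all	TW|JPL, CBTY2, CBRY2, CBTY1, SMP	TW
rbcL	all	TW|JPL, CBTY2, CBRY2, CBTY1, SMP	TW
psbI	all	TW|JPL, CBTY2|CBRY2, CBTY1, SMP	TW2
petD	all	TW|JPL, CBTY2|CBRY2, CBTY1, SMP	TW2
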