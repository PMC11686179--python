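product_id	position	reaction_id
12ppd_S	0	EX_12ppd_S(e)
12ppd_S	1	12PPDt
ac	0	EX_ac(e)
ac	1	ACt2r
acgam	0	EX_acgam(e)
acgam	1	ACGAMt2r
acgam	2	ACGAMCAT
acgam	3	ACt2r
acgam	4	EX_ac(e)
acgam	5	NH4t
acgam	6	EX_nh4(e)
acnam	0	EX_acnam(e)
acnam	1	ACNAMt2r
acnam	2	ACNAMCAT
acnam	3	PYRt2r
acnam	4	EX_pyr(e)
fuc_L	0	EX_fuc_L(e)
fuc_L	1	FUCt2r
fuc_L	2	FUCCAT
fuc_L	3	PYRt2r
fuc_L	4	EX_pyr(e)
fuc_L	5	12PPDt
fuc_L	6	EX_12ppd_S(e)
gal	0	EX_gal(e)
gal	1	GALt2r
gal	2	GALCONV
glc_D	0	EX_glc_D(e)
glc_D	1	GLCt2r
glc_D	2	GLCFERM
glc_D	3	L_LACt2r
glc_D	4	EX_lac_L(e)
lac_L	0	EX_lac_L(e)
lac_L	1	L_LACt2r
lcts	0	EX_lcts(e)
lcts	1	LCTSt2r
lcts	2	LACZ
nh4	0	EX_nh4(e)
nh4	1	NH4t
pyr	0	EX_pyr(e)
pyr	1	PYRt2r
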