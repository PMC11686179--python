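id	name	formula	charge	compartment	class
12ppd_S[c]	(S)-1,2-propanediol	C3H8O2	0	c	product
12ppd_S[e]	(S)-1,2-propanediol	C3H8O2	0	e	product
2fl[c]	2'-fucosyllactose	C18H32O15	0	c	HMO
2fl[e]	2'-fucosyllactose	C18H32O15	0	e	HMO
3fl[c]	3-fucosyllactose	C18H32O15	0	c	HMO
3fl[e]	3-fucosyllactose	C18H32O15	0	e	HMO
3sl[c]	3'-sialyllactose	C23H39NO19	0	c	HMO
3sl[e]	3'-sialyllactose	C23H39NO19	0	e	HMO
6sl[c]	6'-sialyllactose	C23H39NO19	0	c	HMO
6sl[e]	6'-sialyllactose	C23H39NO19	0	e	HMO
ac[c]	acetate	C2H3O2	-1	c	product
ac[e]	acetate	C2H3O2	-1	e	product
acgam[c]	N-acetyl-D-glucosamine	C8H15NO6	0	c	sugar
acgam[e]	N-acetyl-D-glucosamine	C8H15NO6	0	e	sugar
acnam[c]	N-acetylneuraminate	C11H18NO9	-1	c	sugar
acnam[e]	N-acetylneuraminate	C11H18NO9	-1	e	sugar
adp[c]	ADP	C10H12N5O10P2	-3	c	cofactor
atp[c]	ATP	C10H12N5O13P3	-4	c	cofactor
dfl[c]	difucosyllactose	C24H42O19	0	c	HMO
dfl[e]	difucosyllactose	C24H42O19	0	e	HMO
dflnh1[e]	difucosyllacto-N-hexaose I	C52H88N2O39	0	e	HMO
dflnh2[e]	difucosyllacto-N-hexaose II	C52H88N2O39	0	e	HMO
dsl[c]	disialyllactose	C34H56N2O27	0	c	HMO
dsl[e]	disialyllactose	C34H56N2O27	0	e	HMO
dslnh[e]	disialyllacto-N-hexaose	C62H102N4O47	0	e	HMO
dslnt[c]	disialyllacto-N-tetraose	C48H79N3O37	0	c	HMO
dslnt[e]	disialyllacto-N-tetraose	C48H79N3O37	0	e	HMO
flnh1[c]	fucosyllacto-N-hexaose I	C46H78N2O35	0	c	HMO
flnh1[e]	fucosyllacto-N-hexaose I	C46H78N2O35	0	e	HMO
flnh2[e]	fucosyllacto-N-hexaose II	C46H78N2O35	0	e	HMO
fslnh[e]	fucosylsialyllacto-N-hexaose	C57H95N3O43	0	e	HMO
fuc_L[c]	L-fucose	C6H12O5	0	c	sugar
fuc_L[e]	L-fucose	C6H12O5	0	e	sugar
gal[c]	D-galactose	C6H12O6	0	c	sugar
gal[e]	D-galactose	C6H12O6	0	e	sugar
glc_D[c]	D-glucose	C6H12O6	0	c	sugar
glc_D[e]	D-glucose	C6H12O6	0	e	sugar
h[c]	proton	H	1	c	cofactor
h[e]	proton	H	1	e	cofactor
h2o[c]	water	H2O	0	c	cofactor
h2o[e]	water	H2O	0	e	cofactor
lac_L[c]	L-lactate	C3H5O3	-1	c	product
lac_L[e]	L-lactate	C3H5O3	-1	e	product
lcts[c]	lactose	C12H22O11	0	c	disaccharide
lcts[e]	lactose	C12H22O11	0	e	disaccharide
lndfh1[c]	lacto-N-difucohexaose I	C38H65NO29	0	c	HMO
lndfh1[e]	lacto-N-difucohexaose I	C38H65NO29	0	e	HMO
lndfh2[c]	lacto-N-difucohexaose II	C38H65NO29	0	c	HMO
lndfh2[e]	lacto-N-difucohexaose II	C38H65NO29	0	e	HMO
lnfp1[c]	lacto-N-fucopentaose I	C32H55NO25	0	c	HMO
lnfp1[e]	lacto-N-fucopentaose I	C32H55NO25	0	e	HMO
lnfp2[c]	lacto-N-fucopentaose II	C32H55NO25	0	c	HMO
lnfp2[e]	lacto-N-fucopentaose II	C32H55NO25	0	e	HMO
lnfp3[c]	lacto-N-fucopentaose III	C32H55NO25	0	c	HMO
lnfp3[e]	lacto-N-fucopentaose III	C32H55NO25	0	e	HMO
lnfp5[c]	lacto-N-fucopentaose V	C32H55NO25	0	c	HMO
lnfp5[e]	lacto-N-fucopentaose V	C32H55NO25	0	e	HMO
lnfp6[c]	lacto-N-fucopentaose VI	C32H55NO25	0	c	HMO
lnfp6[e]	lacto-N-fucopentaose VI	C32H55NO25	0	e	HMO
lnh[c]	lacto-N-hexaose	C40H68N2O31	0	c	HMO
lnh[e]	lacto-N-hexaose	C40H68N2O31	0	e	HMO
lnnh[e]	lacto-N-neohexaose	C40H68N2O31	0	e	HMO
lnnt[c]	lacto-N-neotetraose	C26H45NO21	0	c	HMO
lnnt[e]	lacto-N-neotetraose	C26H45NO21	0	e	HMO
lnt[c]	lacto-N-tetraose	C26H45NO21	0	c	HMO
lnt[e]	lacto-N-tetraose	C26H45NO21	0	e	HMO
lsta[c]	sialyllacto-N-tetraose a	C37H62N2O29	0	c	HMO
lsta[e]	sialyllacto-N-tetraose a	C37H62N2O29	0	e	HMO
lstb[c]	sialyllacto-N-tetraose b	C37H62N2O29	0	c	HMO
lstb[e]	sialyllacto-N-tetraose b	C37H62N2O29	0	e	HMO
lstc[c]	sialyllacto-N-tetraose c	C37H62N2O29	0	c	HMO
lstc[e]	sialyllacto-N-tetraose c	C37H62N2O29	0	e	HMO
nh4[c]	ammonium	H4N	1	c	product
nh4[e]	ammonium	H4N	1	e	product
pi[c]	orthophosphate	HO4P	-2	c	cofactor
pyr[c]	pyruvate	C3H3O3	-1	c	product
pyr[e]	pyruvate	C3H3O3	-1	e	product
slnh[c]	sialyllacto-N-hexaose	C51H85N3O39	0	c	HMO
slnh[e]	sialyllacto-N-hexaose	C51H85N3O39	0	e	HMO
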