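hmo_id	mechanism	position	reaction_id
2fl	ABC	0	EX_2fl(e)
2fl	ABC	1	2FLabc
2fl	ABC	2	2FLhy
3fl	ABC	0	EX_3fl(e)
3fl	ABC	1	3FLabc
3fl	ABC	2	3FLhy
3sl	proton-symport	0	EX_3sl(e)
3sl	proton-symport	1	3SLt2
3sl	proton-symport	2	3SLhy
6sl	proton-symport	0	EX_6sl(e)
6sl	proton-symport	1	6SLt2
6sl	proton-symport	2	6SLhy
dfl	ABC	0	EX_dfl(e)
dfl	ABC	1	DFLabc
dfl	ABC	2	DFLhy
dflnh1	extracellular-hydrolysis	0	EX_dflnh1(e)
dflnh1	extracellular-hydrolysis	1	DFLNH1hye
dflnh2	extracellular-hydrolysis	0	EX_dflnh2(e)
dflnh2	extracellular-hydrolysis	1	DFLNH2hye
dsl	proton-symport	0	EX_dsl(e)
dsl	proton-symport	1	DSLt2
dsl	proton-symport	2	DSLhy
dslnh	extracellular-hydrolysis	0	EX_dslnh(e)
dslnh	extracellular-hydrolysis	1	DSLNHhye
dslnt	proton-symport	0	EX_dslnt(e)
dslnt	proton-symport	1	DSLNTt2
dslnt	proton-symport	2	DSLNThy
flnh1	proton-symport	0	EX_flnh1(e)
flnh1	proton-symport	1	FLNH1t2
flnh1	proton-symport	2	FLNH1hy
flnh2	extracellular-hydrolysis	0	EX_flnh2(e)
flnh2	extracellular-hydrolysis	1	FLNH2hye
fslnh	extracellular-hydrolysis	0	EX_fslnh(e)
fslnh	extracellular-hydrolysis	1	FSLNHhye
lndfh1	proton-symport	0	EX_lndfh1(e)
lndfh1	proton-symport	1	LNDFH1t2
lndfh1	proton-symport	2	LNDFH1hy
lndfh2	proton-symport	0	EX_lndfh2(e)
lndfh2	proton-symport	1	LNDFH2t2
lndfh2	proton-symport	2	LNDFH2hy
lnfp1	ABC	0	EX_lnfp1(e)
lnfp1	ABC	1	LNFP1abc
lnfp1	ABC	2	LNFP1hy
lnfp2	ABC	0	EX_lnfp2(e)
lnfp2	ABC	1	LNFP2abc
lnfp2	ABC	2	LNFP2hy
lnfp3	ABC	0	EX_lnfp3(e)
lnfp3	ABC	1	LNFP3abc
lnfp3	ABC	2	LNFP3hy
lnfp5	ABC	0	EX_lnfp5(e)
lnfp5	ABC	1	LNFP5abc
lnfp5	ABC	2	LNFP5hy
lnfp6	ABC	0	EX_lnfp6(e)
lnfp6	ABC	1	LNFP6abc
lnfp6	ABC	2	LNFP6hy
lnh	proton-symport	0	EX_lnh(e)
lnh	proton-symport	1	LNHt2
lnh	proton-symport	2	LNHhy
lnnh	extracellular-hydrolysis	0	EX_lnnh(e)
lnnh	extracellular-hydrolysis	1	LNNHhye
lnnt	ABC	0	EX_lnnt(e)
lnnt	ABC	1	LNNTabc
lnnt	ABC	2	LNNThy
lnt	ABC	0	EX_lnt(e)
lnt	ABC	1	LNTabc
lnt	ABC	2	LNThy
lsta	ABC	0	EX_lsta(e)
lsta	ABC	1	LSTAabc
lsta	ABC	2	LSTAhy
lstb	proton-symport	0	EX_lstb(e)
lstb	proton-symport	1	LSTBt2
lstb	proton-symport	2	LSTBhy
lstc	proton-symport	0	EX_lstc(e)
lstc	proton-symport	1	LSTCt2
lstc	proton-symport	2	LSTChy
slnh	proton-symport	0	EX_slnh(e)
slnh	proton-symport	1	SLNHt2
slnh	proton-symport	2	SLNHhy
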