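reaction_id	dg0_prime_kj_mol	kcat_s	km_mM	mw_g_mol	source
glf	0.0	100	glc_e:40.21,xyl_e:80.96,glc:40.21,xyl:80.96	50000	synthetic
glk	-17.1	300	glc:0.3,atp:0.8,g6p:0.5,adp:0.5	70000	synthetic
g6pdh	1.5	200	g6p:0.2,nadp:0.05,6pgl:0.5,nadph:0.05	110000	synthetic
pgl	-21.9	150	6pgl:0.3,6pg:0.8	40000	synthetic
edd	-5.9	120	6pg:0.5,kdpg:0.6	130000	synthetic
eda	15.5	180	kdpg:0.3,pyr:5.0,gap:1.0	70000	synthetic
gapdh	7.0	90	gap:0.8,nad:0.1,pi:2.0,bpg:0.1,nadh:0.05	140000	synthetic
pgk	-18.9	400	bpg:0.1,adp:0.3,3pg:1.0,atp:0.6	45000	synthetic
pgm	4.2	300	3pg:0.5,2pg:0.3	56000	synthetic
eno	-3.8	200	2pg:0.1,pep:0.3	90000	synthetic
pyk	-31.7	250	pep:0.3,adp:0.3,pyr:5.0,atp:1.0	230000	synthetic
als	-43.0	100	pyr:8.0	120000	synthetic
aldc	-21.0	80	alac:2.0	70000	synthetic
bdh	-23.5	120	actn:1.5,nadh:0.04,bdo:3.0,nad:0.2	100000	synthetic
xyl	2.0	30	xyl:5.0,xlu:5.0	180000	synthetic
xk	-10.0	100	xlu:0.5,atp:0.5,x5p:1.0,adp:0.5	110000	synthetic
rpe	3.4	200	x5p:1.0,ru5p:1.0	50000	synthetic
rpi	-1.5	250	ru5p:0.8,r5p:1.5	45000	synthetic
tkt1	-3.8	60	x5p:0.3,r5p:0.4,s7p:1.0,gap:1.0	140000	synthetic
tal	-0.9	100	s7p:0.3,gap:1.0,e4p:0.3,f6p:1.2	70000	synthetic
tkt2	-9.6	60	x5p:0.3,e4p:0.1,f6p:1.5,gap:1.0	140000	synthetic
pgi	-2.5	400	f6p:0.3,g6p:1.0	120000	synthetic
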