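# Terpene panel: one row per analyte.
# Columns: index, name, compound_class, target_mz, qualifier_mz1, qualifier_mz2,
#          calibration_mix, isomer_fraction, reference_rt_min, assigned_istd,
#          model_kind, split_point_ug (empty if none), range_top_ug
index	name	compound_class	target_mz	qualifier_mz1	qualifier_mz2	calibration_mix	isomer_fraction	reference_rt_min	assigned_istd	model_kind	split_point_ug	range_top_ug
1	alpha-pinene	monoterpene	93	121	136	mix1	1.0	18.8	decane	entire		10.0
2	camphene	monoterpene	93	77	121	mix1	1.0	20.0	decane	entire		10.0
3	sabinene	monoterpene	93	77	136	mix1	1.0	21.1	decane	entire		10.0
4	beta-myrcene	monoterpene	93	121	136	mix1	1.0	21.4	decane	entire		10.0
5	beta-pinene	monoterpene	93	69	77	mix1	1.0	21.5	decane	entire		10.0
6	alpha-phellandrene	monoterpene	93	91	136	mix4	1.0	23.0	decane	entire		10.0
7	3-carene	monoterpene	93	121	77	mix1	1.0	23.1	decane	entire		10.0
8	alpha-terpinene	monoterpene	121	93	136	mix1	1.0	23.7	decane	entire		10.0
9	cis-beta-ocimene	monoterpene	93	91	79	mix1	0.28	24.2	decane	entire		10.0
10	m-cymene	monoterpene	119	134	117	mix1	1.0	24.3	decane	entire		10.0
11	limonene	monoterpene	68	93	121	mix1	1.0	24.5	decane	entire		10.0
12	p-cymene	monoterpene	119	117	115	mix1	1.0	24.7	decane	entire		10.0
13	trans-beta-ocimene	monoterpene	93	79	121	mix1	0.72	25.2	decane	entire		10.0
14	eucalyptol	monoterpenoid	108	111	154	mix1	1.0	25.5	decane	entire		10.0
15	o-cymene	monoterpene	119	134	91	mix1	1.0	25.8	decane	entire		10.0
16	gamma-terpinene	monoterpene	93	121	79	mix1	1.0	26.5	decane	entire		10.0
17	terpinolene	monoterpene	93	121	136	mix1	1.0	29.0	undecane	entire		10.0
18	trans-sabinene-hydrate	monoterpenoid	93	71	121	mix1	1.0	30.4	undecane	split	1.00	10.0
19	linalool	monoterpenoid	71	93	121	mix1	1.0	32.4	undecane	split	1.00	10.0
20	fenchone	monoterpenoid	81	69	152	mix2	1.0	33.1	undecane	restricted		5.00
21	endo-fenchol	monoterpenoid	81	80	69	mix1	1.0	35.8	undecane	split	1.00	10.0
22	isopulegol	monoterpenoid	81	121	80	mix1	1.0	36.9	dodecane	split	1.00	10.0
23	camphor	monoterpenoid	95	81	108	mix2	1.0	37.5	dodecane	restricted		5.00
24	isoborneol	monoterpenoid	95	121	110	mix2	1.0	37.8	dodecane	split	1.00	10.0
25	terpinene-4-ol	monoterpenoid	71	111	93	mix1	1.0	37.8	dodecane	split	1.00	10.0
26	menthol	monoterpenoid	81	95	71	mix2	1.0	37.9	dodecane	split	1.00	10.0
27	borneol	monoterpenoid	95	110	93	mix3	1.0	38.1	dodecane	split	1.75	10.0
28	alpha-terpineol	monoterpenoid	93	121	81	mix1	1.0	38.4	dodecane	split_restricted	1.00	7.50
29	pulegone	monoterpenoid	81	69	93	mix2	1.0	39.7	tridecane	entire		10.0
30	thymol	monoterpenoid	135	150	115	mix1	1.0	41.0	tridecane	split_restricted	0.500	7.50
31	carvacrol	monoterpenoid	135	150	151	mix1	1.0	41.3	tridecane	split_restricted	0.500	7.50
32	geranyl-acetate	monoterpenoid	69	93	121	mix2	1.0	41.6	tetradecane	split	1.00	10.0
33	trans-beta-farnesene	sesquiterpene	69	67	81	mix1	1.0	42.7	tetradecane	entire		10.0
34	alpha-cedrene	sesquiterpene	119	105	204	mix2	1.0	42.9	tetradecane	restricted		5.00
35	beta-caryophyllene	sesquiterpene	93	161	120	mix3	1.0	43.0	tetradecane	entire		10.0
36	beta-cedrene	sesquiterpene	161	93	120	mix1	0.20	43.2	tetradecane	entire		10.0
37	alpha-humulene	sesquiterpene	93	80	121	mix2	1.0	43.7	pentadecane	entire		10.0
38	valencene	sesquiterpene	161	175	176	mix4	1.0	44.3	pentadecane	restricted		5.00
39	cis-nerolidol	sesquiterpenoid	69	93	107	mix3	1.0	44.7	pentadecane	split	1.75	10.0
40	selina-3,7-(11)-diene	sesquiterpene	161	122	204	spike	1.0	45.4	hexadecane	split_restricted	1.00	7.50
41	guaiol	sesquiterpenoid	161	197	93	mix1	1.0	47.0	hexadecane	split	1.00	10.0
42	caryophyllene-oxide	sesquiterpenoid	79	93	107	mix4	1.0	47.5	heptadecane	split	1.75	10.0
43	alpha-cedrol	sesquiterpenoid	95	150	151	mix2	1.0	48.1	heptadecane	split	1.75	10.0
44	alpha-bisabolol	sesquiterpenoid	69	109	119	mix2	1.0	48.8	heptadecane	split	1.75	10.0
45	beta-eudesmol	sesquiterpenoid	59	149	164	mix3	1.0	49.1	heptadecane	split	1.75	10.0
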