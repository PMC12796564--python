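# Published validation results per analyte (instrument-derived reference data,
# not reproducible from this package): DIN 32645 analytical limits in ug absolute
# amount in vial, accuracy (bias, %) and intra-/inter-day precision (RSD, %)
# at the low and high QC level (n = 8 days in duplicate).
index	name	lod_ug	loq_ug	bias_low	bias_high	intra_low	intra_high	inter_low	inter_high
1	alpha-pinene	0.00844	0.0292	10.2	0.87	4.7	3.0	6.9	4.9
2	camphene	0.00758	0.0262	10.0	0.86	3.7	4.9	5.0	5.8
3	sabinene	0.00762	0.0263	8.3	2.6	4.2	3.7	7.0	4.4
4	beta-myrcene	0.00666	0.0231	7.7	1.9	5.1	4.3	7.5	4.3
5	beta-pinene	0.00826	0.0286	6.4	1.7	5.0	3.6	8.9	4.7
6	alpha-phellandrene	0.00697	0.0241	10.4	-0.84	2.9	3.0	6.5	5.5
7	3-carene	0.00813	0.0281	7.3	-3.7	3.2	6.1	7.4	9.6
8	alpha-terpinene	0.00670	0.0229	8.9	3.8	6.0	3.9	8.1	4.2
9	cis-beta-ocimene	0.00283	0.00980	9.2	0.38	3.8	5.0	6.8	8.1
10	m-cymene	0.00830	0.0287	3.9	3.3	6.6	4.3	11.2	4.3
11	limonene	0.00689	0.0239	7.8	1.6	5.2	3.8	8.0	4.2
12	p-cymene	0.00789	0.0273	3.9	3.8	6.2	3.5	10.8	3.5
13	trans-beta-ocimene	0.00573	0.0198	7.6	3.8	4.0	4.2	8.2	4.6
14	eucalyptol	0.00835	0.0289	5.2	-2.0	6.4	5.5	11.0	7.5
15	o-cymene	0.00861	0.0290	4.5	1.5	5.2	4.6	10.0	5.0
16	gamma-terpinene	0.00828	0.0286	6.7	-0.51	6.5	6.3	7.7	7.4
17	terpinolene	0.00601	0.0209	6.5	-0.64	5.9	4.9	10.0	4.9
18	trans-sabinene-hydrate	0.00823	0.0284	-6.5	-6.3	7.2	8.5	11.9	8.5
19	linalool	0.00609	0.0212	4.2	-5.4	7.2	7.4	10.1	7.5
20	fenchone	0.00731	0.0252	5.2	-4.7	3.5	8.5	5.1	9.4
21	endo-fenchol	0.00792	0.0273	2.3	-6.9	7.8	7.0	11.6	7.0
22	isopulegol	0.00720	0.0249	9.5	-8.5	6.7	6.4	6.7	6.4
23	camphor	0.00827	0.0286	6.3	-4.2	3.5	8.1	6.3	9.2
24	isoborneol	0.00839	0.0290	2.6	-4.2	4.2	9.7	10.2	9.8
25	terpinene-4-ol	0.00815	0.0282	-0.5	-5.0	7.7	6.9	11.2	6.9
26	menthol	0.00827	0.0286	4.0	-5.0	4.2	9.4	5.2	9.4
27	borneol	0.00789	0.0273	-6.2	-5.5	10.6	8.9	10.6	8.9
28	alpha-terpineol	0.00761	0.0263	6.4	-4.3	4.5	7.2	7.6	7.5
29	pulegone	0.00605	0.0210	8.4	0.78	1.9	8.3	4.6	10.8
30	thymol	0.00753	0.0260	5.8	-2.0	10.8	9.9	10.8	10.0
31	carvacrol	0.00719	0.0249	7.0	-1.2	9.5	11.8	9.5	11.8
32	geranyl-acetate	0.00824	0.0285	-2.2	-1.3	11.6	12.3	11.6	12.3
33	trans-beta-farnesene	0.00713	0.0247	3.0	5.0	8.5	4.9	10.6	4.9
34	alpha-cedrene	0.00383	0.0135	-1.5	7.5	3.3	4.4	6.5	7.6
35	beta-caryophyllene	0.00790	0.0273	-2.4	-2.7	2.8	3.5	13.2	5.0
36	beta-cedrene	0.00224	0.00783	9.5	-2.1	4.3	11.1	4.9	11.1
37	alpha-humulene	0.00293	0.0104	6.9	4.3	1.6	5.1	4.3	6.2
38	valencene	0.00813	0.0281	7.4	3.0	2.3	4.5	4.5	9.2
39	cis-nerolidol	0.00786	0.0271	3.9	-1.7	4.0	9.0	7.4	9.5
40	selina-3,7-(11)-diene	0.00839	0.0290	1.8	-2.0	5.0	0.0	7.5	7.2
41	guaiol	0.00782	0.0270	11.3	-10.0	5.4	4.7	5.4	4.7
42	caryophyllene-oxide	0.00518	0.0181	-5.1	-5.0	6.4	3.6	12.5	8.4
43	alpha-cedrol	0.00608	0.0211	-7.3	-8.5	7.4	4.9	10.6	5.8
44	alpha-bisabolol	0.00818	0.0283	10.6	-9.7	3.5	3.1	5.2	5.1
45	beta-eudesmol	0.00668	0.0232	6.2	-3.9	4.9	9.6	5.3	9.6
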