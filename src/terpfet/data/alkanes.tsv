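# n-alkane retention-index ladder used as internal standard (ISTD).
# vial_amount_ug: absolute amount spiked per vial (2 uL of the RT index mix;
# all components 100 ug/mL except pentadecane at 200 ug/mL).
carbon_number	name	reference_rt_min	vial_amount_ug	target_mz	qualifier_mz
10	decane	21.2	0.2	142	113
11	undecane	28.4	0.2	156	127
12	dodecane	36.8	0.2	170	127
13	tridecane	39.5	0.2	184	127
14	tetradecane	41.4	0.2	198	155
15	pentadecane	43.2	0.4	212	169
16	hexadecane	45.1	0.2	226	169
17	heptadecane	47.2	0.2	240	155
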