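locus	gene	chromosome	trigger	start	end	n	k	p_value
At1g62910	RFL9_PPR	1	TAS2_3p-D6(-)	23299624	23299875	77	14	2.0e-7
At1g63130	RPF6	1	ta-siR2140	23413391	23413642	13	7	7.3e-7
At1g50055	TAS1B	1	miR173	18549441	18549692	60	12	9.7e-7
At1g63070	PPR	1	ta-siR2140	23386420	23386671	50	11	1.3e-6
At1g63150	.	1	TAS2_3p-D6(-)	23420003	23420254	80	12	2.7e-5
At1g62930	RPF3_PPR	1	miR161.1	23307125	23307466	99	13	4.5e-5
At1g63080	PPR	1	ta-siR2140	23389990	23390241	58	10	5.5e-5
At1g62590	PPR-AC	1	TAS2_3p-D6(-)	23178438	23178689	27	7	7.1e-5
At2g39681	TAS2	2	miR173	16539919	16540170	12	9	1.9e-9
At2g39675	TAS1C	2	miR173	16537860	16538111	10	7	1.5e-8
At2g27400	TAS1A	2	miR173	11722009	11722260	21	8	6.2e-7
At3g17185	TAS3	3	miR390	5682143	5682394	80	14	3.4e-7
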