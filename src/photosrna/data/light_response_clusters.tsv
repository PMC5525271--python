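srna_id	cluster	W0	W1	W3	W6	W12	W24
miR163	I	0	3.230582	5.070049	6.036598	5.963276	6.724631
miR5026	II	0	-0.19729	0.609021	-0.33921	0.435821	0.256526
miR825	II	0	-0.55657	-0.0974	0.484967	0.475439	0.143117
miR869.2	II	0	-0.44551	-0.24714	0.236649	-0.06937	0.766993
miR156c-3p	II	0	0.008901	0.458674	-0.41258	0.129615	0.571201
miR170-3p	II	0	0.199128	0.233507	0.359504	0.420726	-0.0398
miR2933a	II	0	-0.73393	0.087544	0.296233	-0.12048	0.00611
miR2933b	II	0	-0.73393	0.087544	0.296233	-0.12048	0.00611
miR5642a	II	0	-0.12856	0.102902	0.354152	0.920248	0.760898
miR157d	II	0	0.366314	0.311192	0.17222	0.304513	0.640368
miR167a-3p	II	0	0.046902	0.474899	0.574704	0.480747	0.881156
miR833b	II	0	1.053165	0.727714	0.849033	0.892631	0.279323
miR858a	II	0	0.657713	0.522465	0.833586	0.69362	0.780516
miR157a-3p	II	0	0.119139	0.300398	0.181048	0.842913	1.197978
miR157b-3p	II	0	0.112265	0.292249	0.169389	0.833254	1.186319
miR157c-3p	II	0	0.18009	0.174448	1.165619	1.299035	2.35774
miR158b	III	0	0.068148	-0.23119	0.046673	-0.49671	-0.77436
miR162a-3p	III	0	0.216902	-0.35089	-0.001	-0.53321	-1.32163
miR390a-5p	III	0	0.041912	-0.24039	-0.52191	-0.83531	-0.94731
miR398c-3p	III	0	0.233205	-0.74225	0.337007	-0.5905	-1.54736
miR399b	III	0	-0.32628	-0.03547	-0.57065	-0.81218	-1.16872
miR399c-3p	III	0	-0.13086	0.021596	-0.5015	-0.75814	-1.10903
miR829-3p.1	III	0	-0.19326	-0.0353	-0.14504	-0.74384	-0.90991
miR829-5p	III	0	0.017165	-0.29223	-0.32674	-0.66067	-0.74456
miR162b-3p	III	0	0.215734	-0.35239	-0.00193	-0.53434	-1.32203
miR162b-5p	III	0	0.057888	-0.1911	0.175723	-0.742	-1.07194
miR169a-3p	III	0	-0.35672	-0.10399	-0.09992	-0.43079	-0.99436
miR173-5p	III	0	-0.04189	-0.26578	-0.30136	-0.5118	-0.95313
miR390b-5p	III	0	0.041759	-0.2396	-0.52135	-0.83081	-0.94673
miR396b-3p	III	0	-0.19923	-0.26739	-0.52009	-0.66862	-1.11049
miR398b-3p	III	0	0.233205	-0.74225	0.337007	-0.5905	-1.54736
miR823	III	0	-0.25067	0.109541	-0.45625	-0.76484	-0.99271
miR839-5p	III	0	-0.9158	0.276875	-0.35478	-0.56659	-1.1664
miR166a-3p	III	0	0.141355	0.079493	-0.11147	-0.50323	-0.56368
miR166b-3p	III	0	0.158125	0.078693	-0.10249	-0.52608	-0.57401
miR166c	III	0	0.157754	0.078204	-0.10279	-0.52633	-0.57431
miR166d	III	0	0.1578	0.078219	-0.1028	-0.52637	-0.5743
miR166e-3p	III	0	0.157828	0.07835	-0.10235	-0.52615	-0.57403
miR166f	III	0	0.157829	0.078349	-0.10233	-0.5261	-0.574
miR166g	III	0	0.157513	0.077882	-0.10266	-0.52644	-0.57431
miR169b-3p	III	0	0.046702	0.084603	-0.51457	0.08493	-0.43209
miR169i	III	0	-0.21387	0.036407	-0.3923	-0.08524	-0.29972
miR171c-5p	III	0	-0.24785	-0.51146	-0.30205	-0.45579	-0.08671
miR319b	III	0	0.101478	0.007334	0.230599	-0.43223	-0.64435
miR393b-3p	III	0	-0.22189	-0.24646	-0.14695	-0.49096	-0.49076
miR408-3p	III	0	-0.24897	-0.16535	0.122217	-0.11517	-0.57962
miR5644	III	0	-0.46437	-0.21745	-0.08393	-0.26968	-0.45617
miR156h	III	0	-0.44634	-0.37253	-0.19148	-0.36689	-0.10394
miR160c-3p	III	0	-0.17658	-0.29051	-0.33976	-0.00825	0.041016
miR169m	III	0	-0.12627	0.064869	-0.27125	0.118007	-0.32789
miR166a-5p	III	0	-0.14566	-0.30587	-0.69082	-1.16879	-1.42452
miR395e	III	0	-0.52798	-0.63659	-0.291	-1.43631	-1.91425
miR5646	III	0	-0.55674	-0.18855	-0.6301	-1.65092	-1.82573
miR166b-5p	III	0	-0.14566	-0.30587	-0.69082	-1.16879	-1.42452
miR166e-5p	III	0	-0.49789	-0.68724	-1.10023	-1.47964	-1.73891
miR390b-3p	III	0	-0.32255	-0.76324	-0.65686	-1.66625	-1.99135
miR395a	III	0	-0.52798	-0.63659	-0.29058	-1.43631	-1.91425
miR395b	III	0	-0.30231	-0.53107	-0.43895	-1.02895	-2.04242
miR395c	III	0	-0.30231	-0.53107	-0.43895	-1.02895	-2.04242
miR395d	III	0	-0.52798	-0.63659	-0.29058	-1.43631	-1.91425
miR395f	III	0	-0.30231	-0.57998	-0.43895	-1.02895	-2.04242
miR396a-3p	III	0	-0.16376	-0.71517	-0.7776	-1.56218	-2.04976
miR408-5p	III	0	-0.44974	-0.17004	-0.65167	-1.20912	-1.72316
miR5012	III	0	-0.37776	-0.43595	-0.68763	-1.5225	-1.78667
miR5024-3p	III	0	-0.59768	-0.10816	-0.63027	-1.32052	-2.05354
miR5634	III	0	-0.19003	-0.51725	-0.68077	-0.88666	-1.19981
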