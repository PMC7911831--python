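# Annotated CDS of halovirus Hardycor1, transcribed from the published
# GenBank annotation of accession MT152698 (coordinates 1-based inclusive;
# Length is the CDS span in nt; genome is 45,142 bp, circular assembly).
Start	Stop	Locus_Tag	Length	Direction
138	791	HrrHc1_005	654	+
788	1012	HrrHc1_010	225	+
1009	1323	HrrHc1_015	315	+
1320	1883	HrrHc1_020	564	+
1880	2260	HrrHc1_025	381	+
2337	3560	HrrHc1_030	1224	+
3809	5407	HrrHc1_035	1599	+
5412	7382	HrrHc1_040	1971	+
7479	8501	HrrHc1_045	1023	+
8506	8820	HrrHc1_050	315	-
8986	10470	HrrHc1_055	1485	+
10474	10911	HrrHc1_060	438	+
10913	11989	HrrHc1_065	1077	+
12070	12501	HrrHc1_070	432	+
12505	12933	HrrHc1_075	429	+
12935	13288	HrrHc1_080	354	+
13285	13710	HrrHc1_085	426	+
13707	14201	HrrHc1_090	495	+
14337	15266	HrrHc1_095	930	-
15676	15879	HrrHc1_100	204	+
15883	17115	HrrHc1_105	1233	+
17143	17613	HrrHc1_110	471	+
17688	17894	HrrHc1_115	207	+
17894	20005	HrrHc1_120	2112	+
20007	20552	HrrHc1_125	546	+
20554	21759	HrrHc1_130	1206	+
21756	22067	HrrHc1_135	312	+
22069	22527	HrrHc1_140	459	+
22599	24518	HrrHc1_145	1920	+
24574	24813	HrrHc1_150	240	+
24825	25175	HrrHc1_155	351	+
25290	26255	HrrHc1_160	966	+
26324	26917	HrrHc1_165	594	+
27104	27502	HrrHc1_170	399	-
27499	27936	HrrHc1_175	438	-
28034	28390	HrrHc1_180	357	-
28390	28674	HrrHc1_185	285	-
28671	29117	HrrHc1_190	447	-
29114	29314	HrrHc1_195	201	-
29311	29610	HrrHc1_200	300	-
29607	29867	HrrHc1_205	261	-
29860	31395	HrrHc1_210	1536	-
31392	32585	HrrHc1_215	1194	-
32774	32938	HrrHc1_220	165	-
32935	33327	HrrHc1_225	393	-
33324	35321	HrrHc1_230	1998	-
35523	37079	HrrHc1_235	1557	-
37288	38694	HrrHc1_240	1407	-
38836	40968	HrrHc1_245	2133	-
41082	42461	HrrHc1_250	1380	-
42458	43084	HrrHc1_255	627	-
43162	43923	HrrHc1_260	762	+
44232	44936	HrrHc1_265	705	+
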