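prot_id	node_id	detected	control	day4	day10	day15	predicted_function	expected_high
1399288	209	D10,D15	11.43	13.63	13.92	13.34	AA3_2 GMC oxidoreductase	LHHH
855582	267	D10,D15	6.47	9.20	8.51	8.46	AA2 MnP-short	LLLL
1353775	331	D15	6.91	9.39	11.21	8.98	AA5_1 copper radical oxidase	LLLL
1343556	349	D4,D10,D15	12.06	12.84	13.27	13.28	AA3_2 GMC oxidoreductase	HHHH
1486819	372	D4,D10,D15	8.52	16.89	14.66	12.89	AA2 MnP-short	LHHH
1359988	400	D4,D10,D15	6.73	17.36	10.29	7.41	AA2 VP	LHLL
1422328	416	D10,D15	15.27	15.94	16.52	14.83	AA3_2 GMC oxidoreductase	HHHH
1364967	417	D10,D15	10.76	17.12	16.14	15.71	AA3_3 GMC oxidoreductase	LHHH
1487275	417	D4,D10,D15	9.84	18.95	17.82	15.66	AA2 VP	LHHH
713930	418	D10,D15	8.38	17.61	18.31	17.41	AA5_1 copper radical oxidase	LHHH
897918	418	D4,D10,D15	8.06	15.10	16.76	16.49	AA2 VP	LHHH
1412926	418	D4,D10,D15	7.42	14.95	17.04	16.86	AA2 VP	LHHH
1557562	418	D4,D10,D15	6.06	16.87	17.30	16.83	AA5_1 copper radical oxidase	LHHH
918032	419	D4	7.31	17.99	14.98	10.42	AA2 VP	LHHL
1360396	419	D4,D10,D15	6.40	18.95	14.78	12.07	AA2 VP	LHHH
1185543	420	D4,D10,D15	7.00	12.95	15.69	16.08	AA2 MnP-short	LHHH
1347226	420	D4,D10,D15	6.63	12.72	15.16	16.27	AA2 MnP-short	LHHH
1487292	422	D10,D15	5.49	15.94	12.94	8.21	AA2 MnP-short	LHHL
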