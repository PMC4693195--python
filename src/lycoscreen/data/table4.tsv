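Std	Run	A	B	C	D	E	F	G	H	J	K	L	M	N	O	P	Q	R	S	T	U	V	W	X	Lycopene	Biomass	Lycopene_content	Lipid	Lipid_content
12	1	0.006	0.006	1	1	5	6	2	0.5	0.1	0.01	0.05	5	5	5	5	5	1	5	1	10	10	20	20	9.99	13.35	0.75	1.27	9.51
16	2	0.006	0.006	1	1	5	12	0.5	0.5	2	0.01	0.3	1	1	1	1	5	5	5	10	10	1	60	20	34.51	26.73	1.29	2.41	9.02
4	3	0.0006	0.0006	1	5	5	12	2	2	0.1	0.1	0.05	5	5	1	1	5	5	1	1	10	1	60	20	27.87	19.48	1.43	2.2	11.3
6	4	0.006	0.0006	1	1	1	12	2	2	2	0.1	0.05	5	1	5	5	1	1	5	10	1	1	60	20	9.85	27.4	0.36	1.57	5.73
20	5	0.006	0.0006	5	1	5	12	0.5	0.5	2	0.1	0.05	1	5	1	5	1	1	1	1	10	10	60	60	6.69	30.88	0.22	1.6	5.18
22	6	0.006	0.006	5	1	5	6	2	2	0.1	0.01	0.3	5	1	1	5	1	5	1	1	1	1	60	60	18.47	31.45	0.59	1.02	3.24
8	7	0.006	0.0006	5	1	1	6	0.5	2	2	0.1	0.3	5	1	5	1	5	5	1	1	10	10	20	20	41.23	14.23	2.9	1.55	10.9
24	8	0.0006	0.0006	1	1	1	6	0.5	0.5	0.1	0.01	0.05	1	1	1	1	1	1	1	1	1	1	20	20	40.54	16.53	2.45	1.53	9.23
18	9	0.006	0.0006	5	5	1	6	2	2	0.1	0.01	0.3	1	5	1	1	1	1	5	10	10	10	60	20	19.95	29.05	0.69	1.63	5.61
13	10	0.0006	0.006	5	1	1	12	0.5	2	0.1	0.01	0.05	1	5	5	5	5	5	1	10	1	10	60	20	12.41	30.58	0.41	0.82	2.68
3	11	0.0006	0.0006	5	5	5	12	2	0.5	2	0.01	0.3	5	1	1	5	5	1	1	10	1	10	20	20	2.07	21.05	0.1	1.45	6.86
5	12	0.0006	0.0006	1	1	5	12	2	2	2	0.01	0.3	1	5	5	1	1	5	5	1	1	10	20	60	9.8	33.23	0.3	1.4	4.21
7	13	0.0006	0.006	1	1	1	6	2	2	2	0.1	0.3	1	5	1	5	5	1	1	10	10	1	20	60	23.58	23.65	1	1.62	6.85
2	14	0.0006	0.006	5	5	5	12	0.5	2	0.1	0.1	0.3	1	1	5	5	1	1	5	1	10	1	20	20	16.44	21.33	0.77	0.88	4.13
19	15	0.0006	0.006	1	5	5	6	0.5	2	2	0.01	0.05	5	1	5	1	1	1	1	10	10	10	60	60	1.77	9.08	0.2	1.09	12.01
9	16	0.0006	0.006	1	5	1	6	0.5	0.5	2	0.1	0.3	5	5	1	5	1	5	5	1	1	10	60	20	4.09	21.3	0.19	1.56	7.3
15	17	0.006	0.0006	1	5	5	6	0.5	2	0.1	0.1	0.05	1	1	1	5	5	5	5	10	1	10	20	60	12.36	29.13	0.42	1.44	4.93
14	18	0.0006	0.0006	5	5	1	6	2	0.5	2	0.01	0.05	1	1	5	5	5	5	5	1	10	1	60	60	11.14	24.75	0.45	1.56	6.3
10	19	0.0006	0.0006	5	1	5	6	0.5	0.5	0.1	0.1	0.3	5	5	5	1	5	1	5	10	1	1	60	60	16.32	35.5	0.46	1.89	5.32
1	20	0.006	0.006	5	5	5	6	2	0.5	2	0.1	0.05	1	5	5	1	1	5	1	10	1	1	20	20	24.84	20.73	1.2	2	9.65
21	21	0.006	0.006	1	5	1	12	2	0.5	0.1	0.1	0.3	1	1	5	1	5	1	1	1	1	10	60	60	9.99	28.65	0.35	2.65	9.23
17	22	0.0006	0.006	5	1	1	12	2	0.5	0.1	0.1	0.05	5	1	1	1	1	5	5	10	10	10	20	60	24.79	32.63	0.76	2.22	6.8
11	23	0.006	0.0006	1	5	1	12	0.5	0.5	0.1	0.01	0.3	5	5	5	5	1	5	1	10	10	1	20	60	22.7	33.83	0.67	1.19	3.52
23	24	0.006	0.006	5	5	1	12	0.5	2	2	0.01	0.05	5	5	1	1	5	1	5	1	1	1	20	60	3.07	27.73	0.11	1.62	5.83
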