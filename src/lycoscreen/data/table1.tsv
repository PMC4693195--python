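Std	Run	A	B	C	D	E	F	G	H	J	K	L	M	N	O	P	Q	R	S	T	U	V	W	X	Biomass	Lycopene	Lycopene_content
10	1	0.03	1	0.4	1.5	0.1	0.01	0.01	0.02	0.01	0.2	2.5	0.1	3	0.2	0.01	20	0	10	10	0.01	0	0.01	1	14.26	1.76	0.12
22	2	0.3	3	0.4	1.5	0.1	0.01	0.15	0.4	0.01	0.01	2.5	0.1	0.02	0.01	1	10	20	0.5	0.5	0.01	0	0.01	1	1.52	0	0
12	3	0.3	3	0.02	1.5	0.1	0.01	0.15	0.02	0.01	0.01	0.1	0.1	3	0.2	1	20	0	10	0.5	10	3.5	0	0.01	3.38	0	0
2	4	0.03	3	0.4	15	0.1	0.1	0.01	0.4	0.01	0.2	2.5	0.01	0.02	0.2	1	10	0	10	0.5	10	0	0	0.01	11.06	1.82	0.16
7	5	0.03	3	0.02	1.5	0.05	0.01	0.15	0.4	0.1	0.2	2.5	0.01	3	0.01	1	20	0	0.5	10	10	0	0	1	2.36	0.6	0.26
13	6	0.03	3	0.4	1.5	0.05	0.1	0.01	0.4	0.01	0.01	0.1	0.01	3	0.2	1	20	20	0.5	10	0.01	3.5	0.01	0.01	2.66	0.37	0.14
1	7	0.3	3	0.4	15	0.1	0.01	0.15	0.02	0.1	0.2	0.1	0.01	3	0.2	0.01	10	20	0.5	10	0.01	0	0	0.01	3.46	1.17	0.34
16	8	0.3	3	0.02	1.5	0.1	0.1	0.01	0.02	0.1	0.01	2.5	0.01	0.02	0.01	0.01	20	20	10	10	10	0	0.01	0.01	2.38	0	0
3	9	0.03	1	0.4	15	0.1	0.1	0.15	0.02	0.1	0.01	2.5	0.1	0.02	0.01	1	20	0	0.5	10	0.01	3.5	0	0.01	2.74	0.04	0.02
15	10	0.3	1	0.02	15	0.1	0.01	0.01	0.4	0.01	0.2	0.1	0.01	0.02	0.01	1	20	20	10	10	0.01	3.5	0	1	2.82	0	0
14	11	0.03	1	0.4	15	0.05	0.01	0.15	0.02	0.1	0.01	0.1	0.01	0.02	0.2	1	20	20	10	0.5	10	0	0.01	1	12.84	3.82	0.3
21	12	0.3	3	0.02	15	0.05	0.1	0.15	0.02	0.01	0.2	2.5	0.01	0.02	0.2	0.01	20	0	0.5	0.5	0.01	3.5	0.01	1	3.76	0.04	0.01
24	13	0.03	1	0.02	1.5	0.05	0.01	0.01	0.02	0.01	0.01	0.1	0.01	0.02	0.01	0.01	10	0	0.5	0.5	0.01	0	0	0.01	0.64	0	0
18	14	0.3	1	0.4	15	0.05	0.01	0.15	0.4	0.01	0.01	2.5	0.01	3	0.01	0.01	10	0	10	10	10	3.5	0.01	0.01	3.52	0	0
19	15	0.03	3	0.02	15	0.1	0.01	0.01	0.4	0.1	0.01	0.1	0.1	0.02	0.2	0.01	10	0	0.5	10	10	3.5	0.01	1	7.36	2.82	0.38
6	16	0.3	1	0.02	1.5	0.05	0.1	0.15	0.4	0.1	0.2	0.1	0.1	0.02	0.2	1	10	0	10	10	0.01	0	0.01	0.01	1.38	0	0
23	17	0.3	3	0.4	15	0.05	0.1	0.01	0.4	0.1	0.01	0.1	0.1	3	0.01	0.01	20	0	10	0.5	0.01	0	0	1	2.4	0	0
5	18	0.03	1	0.02	1.5	0.1	0.1	0.15	0.4	0.1	0.01	2.5	0.01	3	0.2	0.01	10	20	10	0.5	0.01	3.5	0	1	16.14	5.76	0.36
8	19	0.3	1	0.4	1.5	0.05	0.01	0.01	0.4	0.1	0.2	2.5	0.1	0.02	0.2	0.01	20	20	0.5	0.5	10	3.5	0	0.01	4.44	0	0
17	20	0.03	3	0.4	1.5	0.05	0.1	0.15	0.02	0.01	0.2	0.1	0.1	0.02	0.01	0.01	10	20	10	10	10	3.5	0	1	2.76	0	0
4	21	0.03	1	0.02	15	0.1	0.1	0.15	0.4	0.01	0.2	0.1	0.1	3	0.01	0.01	20	20	0.5	0.5	10	0	0.01	0.01	8.3	9.18	1.11
11	22	0.3	1	0.02	15	0.05	0.1	0.01	0.02	0.01	0.01	2.5	0.1	3	0.2	1	10	20	0.5	10	10	0	0	1	11.26	2.17	0.19
9	23	0.03	3	0.02	15	0.05	0.01	0.01	0.02	0.1	0.2	2.5	0.1	3	0.01	1	10	20	10	0.5	0.01	3.5	0.01	0.01	15.16	3.27	0.22
20	24	0.3	1	0.4	1.5	0.1	0.1	0.01	0.02	0.1	0.2	0.1	0.01	3	0.01	1	10	0	0.5	0.5	10	3.5	0.01	1	4.36	0	0
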