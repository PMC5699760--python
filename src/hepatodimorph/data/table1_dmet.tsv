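number	symbol	gene_title	p_value	fold_change	bias
1	SLC3A1	solute carrier family 3 (cystine, dibasic and neutral amino acid transporters, activator of cystine, dibasic and neutral amino acid transport), member 1	7.27E-12	2.35	F
2	CYP7A1	cytochrome P450, family 7, subfamily A, polypeptide 1	1.28E-10	2.1	F
3	ACSL4	acyl-CoA synthetase long-chain family member 4	0.00266	2	F
4	CYP3A7	cytochrome P450, family 3, subfamily A, polypeptide 7	9.35E-08	1.83	F
5	GSTA1	glutathione S-transferase A1	0.000132	1.82	F
6	CYP3A4	cytochrome P450, family 3, subfamily A, polypeptide 4	5.25E-06	1.73	F
7	GSTA2	glutathione S-transferase A2	0.00266	1.69	F
8	UGT2B17	UDP glucuronosyltransferase 2 family, polypeptide B17	0.0002	1.59	M
9	SLC13A1	solute carrier family 13 (sodium/sulfate symporters), member 1	0.0166	1.57	M
10	ADH1A	alcohol dehydrogenase 1A (class I), alpha polypeptide	0.00003	1.53	F
11	CYP2A6	cytochrome P450, family 2, subfamily A, polypeptide 6	0.0147	1.49	F
12	SLC10A1	solute carrier family 10 (sodium/bile acid cotransporter family), member 1	0.00288	1.48	F
13	CYP2A7	cytochrome P450, family 2, subfamily A, polypeptide 7	0.0212	1.46	F
14	GSTA5	glutathione S-transferase A5	0.00496	1.43	F
15	CYP2A13	cytochrome P450, family 2, subfamily A, polypeptide 13	0.0272	1.43	F
16	HMGCR	3-hydroxy-3-methylglutaryl-Coenzyme A reductase	1.03E-06	1.39	F
17	GLYAT	glycine-N-acyltransferase	0.00223	1.38	F
18	SLC16A8	solute carrier family 16, member 8 (monocarboxylic acid transporter 3)	0.0419	1.35	F
19	FMO3	flavin containing monooxygenase 3	0.0025	1.34	F
20	ADH1C	alcohol dehydrogenase 1C (class I), gamma polypeptide	0.00801	1.34	M
21	CYP2B6	cytochrome P450, family 2, subfamily B, polypeptide 6	0.0265	1.33	F
22	ADH4	alcohol dehydrogenase 4 (class II), pi polypeptide	0.0367	1.33	F
23	CYP2B7P1	cytochrome P450, family 2, subfamily B, polypeptide 7 pseudogene 1	0.034	1.32	F
24	ADH1B	alcohol dehydrogenase 1B (class I), beta polypeptide	0.0116	1.31	F
25	EPHX2	epoxide hydrolase 2, cytoplasmic	0.00129	1.3	F
26	CYP3A43	cytochrome P450, family 3, subfamily A, polypeptide 43	0.00074	1.3	F
27	SLCO1B1	solute carrier organic anion transporter family, member 1B1	0.0151	1.29	F
28	CYP39A1	cytochrome P450, family 39, subfamily A, polypeptide 1	0.00138	1.29	F
29	ABCA12	ATP-binding cassette, sub-family A (ABC1), member 12	0.0133	1.29	M
30	SLC5A6	solute carrier family 5 (sodium-dependent vitamin transporter), member 6	8.32E-06	1.29	M
31	SLC16A14	solute carrier family 16, member 14 (monocarboxylic acid transporter 14)	0.0298	1.28	M
32	FMO1	flavin containing monooxygenase 1	4.37E-08	1.27	F
33	ALDH1B1	aldehyde dehydrogenase 1 family, member B1	0.0151	1.27	F
34	CYP3A5	cytochrome P450, family 3, subfamily A, polypeptide 5	0.00455	1.27	F
35	NR1I2	nuclear receptor subfamily 1, group I, member 2	0.00354	1.25	F
36	GNMT	glycine N-methyltransferase	0.0424	1.25	F
37	UGT2B28	UDP glucuronosyltransferase 2 family, polypeptide B28	0.0344	1.25	F
38	UGT2A3	UDP glucuronosyltransferase 2 family, polypeptide A3	0.00407	1.24	F
39	SLC22A7	solute carrier family 22 (organic anion transporter), member 7	0.0103	1.24	F
40	ALDH1A1	aldehyde dehydrogenase 1 family, member A1	0.00812	1.23	F
41	SLC22A1	solute carrier family 22 (organic cation transporter), member 1	0.0125	1.22	F
42	AADAC	arylacetamide deacetylase (esterase)	0.00517	1.22	F
43	BAAT	bile acid Coenzyme A: amino acid N-acyltransferase (glycine N-choloyltransferase)	0.0242	1.22	F
44	CES4	carboxylesterase 4 (monocyte/macrophage serine esterase 4)	0.0158	1.22	F
45	SLCO4A1	solute carrier organic anion transporter family, member 4A1	0.000551	1.22	M
46	ADH7	alcohol dehydrogenase 7 (class IV), mu or sigma polypeptide	0.0252	1.21	F
47	ALDH7A1	aldehyde dehydrogenase 7 family, member A1	0.00186	1.21	F
48	NNMT	nicotinamide N-methyltransferase	0.000628	1.21	M
49	UGT2B10	UDP glucuronosyltransferase 2 family, polypeptide B10	0.0345	1.2	F
50	CBR1	carbonyl reductase 1	0.000228	1.2	F
51	ALDH5A1	aldehyde dehydrogenase 5 family, member A1 (succinate-semialdehyde dehydrogenase)	0.00441	1.2	F
52	CYP51A1	cytochrome P450, family 51, subfamily A, polypeptide 1	0.000344	1.2	F
53	GPX2	glutathione peroxidase 2 (gastrointestinal)	0.000185	1.2	M
54	ORM2	orosomucoid 2	0.0023	1.2	M
55	HNMT	histamine N-methyltransferase	0.00187	1.19	F
56	FMO5	flavin containing monooxygenase 5	0.034	1.19	F
57	MAOB	monoamine oxidase B	0.0106	1.19	F
58	CYP2J2	cytochrome P450, family 2, subfamily J, polypeptide 2	0.00155	1.19	F
59	ORM1	orosomucoid 1	0.00164	1.19	M
60	CHST9	carbohydrate (N-acetylgalactosamine 4-0) sulfotransferase 9	0.00038	1.18	F
61	SLC2A2	solute carrier family 2 (facilitated glucose transporter), member 2	0.0355	1.18	F
62	SLC19A2	solute carrier family 19 (thiamine transporter), member 2	0.0116	1.18	F
63	ABCA2	ATP-binding cassette, sub-family A (ABC1), member 2	4.61E-06	1.17	F
64	SAT1	spermidine/spermine N1-acetyltransferase 1	0.00121	1.17	F
65	SLC16A9	solute carrier family 16, member 9 (monocarboxylic acid transporter 9)	0.0261	1.17	F
66	SLC10A2	solute carrier family 10 (sodium/bile acid cotransporter family), member 2	0.00207	1.17	M
67	ABCA1	ATP-binding cassette, sub-family A (ABC1), member 1	0.000414	1.17	M
68	ACSL1	acyl-CoA synthetase long-chain family member 1	0.0122	1.16	F
69	CYP27A1	cytochrome P450, family 27, subfamily A, polypeptide 1	0.00892	1.16	F
70	CYP4Z1	cytochrome P450, family 4, subfamily Z, polypeptide 1	0.0123	1.16	F
71	GPX3	glutathione peroxidase 3 (plasma)	0.0000818	1.16	M
72	CES1	carboxylesterase 1 (monocyte/macrophage serine esterase 1)	0.018	1.15	F
73	SULT1C2	sulfotransferase family, cytosolic, 1C, member 2	0.0323	1.15	M
74	SLC22A4	solute carrier family 22 (organic cation transporter), member 4	0.00243	1.14	M
75	ABCB1	ATP-binding cassette, sub-family B (MDR/TAP), member 1	4.72E-06	1.13	M
76	SLC22A23	solute carrier family 22, member 23	0.0134	1.13	M
77	CYP1B1	cytochrome P450, family 1, subfamily B, polypeptide 1	0.0152	1.13	M
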