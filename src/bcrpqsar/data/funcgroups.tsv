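bit_index	kind	pattern	min_count	description
0	smarts	[CX4]	1	sp3 carbon
1	smarts	[CX3]=[CX3]	1	alkene
2	smarts	[CX2]#[CX2]	1	alkyne
3	smarts	c	1	aromatic carbon
4	smarts	[nR]	1	aromatic nitrogen in ring (N-heteroaromatic)
5	smarts	[oR]	1	aromatic oxygen in ring
6	smarts	[sR]	1	aromatic sulfur in ring
7	smarts	[N,O;R]	1	aliphatic N or O in ring (saturated heterocycle atom)
8	smarts	[NX3;R]	1	aliphatic ring amine
9	smarts	[OX2;R]	1	aliphatic ring ether
10	smarts	[OX2H]	1	hydroxyl
11	smarts	[OX2H][cX3]	1	phenol
12	smarts	[OX2H][CX4]	1	aliphatic alcohol
13	smarts	[CX3](=O)[OX2H1]	1	carboxylic acid
14	smarts	[CX3](=O)[OX2][#6]	1	ester
15	smarts	[CX3](=O)[NX3]	1	amide
16	smarts	[NX3][CX3](=O)[NX3]	1	urea
17	smarts	[NX3][CX3](=O)[OX2]	1	carbamate
18	smarts	[CX3](=O)[#6]	1	ketone or acyl
19	smarts	[CX3H1](=O)	1	aldehyde
20	smarts	[NX3;H2;!$(NC=O)][#6]	1	primary amine
21	smarts	[NX3;H1;!$(NC=O)]([#6])[#6]	1	secondary amine
22	smarts	[NX3;H0;!$(NC=O);!$(N=O)]([#6])([#6])[#6]	1	tertiary amine
23	smarts	[NX3][CX4]	1	amine on sp3 carbon
24	smarts	[NX2]=[CX3]	1	imine
25	smarts	[NX1]#[CX2]	1	nitrile
26	smarts	[N+](=O)[O-]	1	nitro group
27	smarts	O=[N+]([O-])c1ccccc1	1	nitro-substituted benzene ring
28	smarts	[NX2]=[NX2]	1	azo
29	smarts	[NX3][NX3]	1	hydrazine-like N-N
30	smarts	[NX3]N=[CX3]	1	hydrazone
31	smarts	[NX3][OX2H]	1	hydroxylamine
32	smarts	NC(=N)N	1	guanidine
33	smarts	[SX2H]	1	thiol
34	smarts	[#16X2]([#6])[#6]	1	thioether
35	smarts	[#16X3](=O)[#6]	1	sulfoxide
36	smarts	[#16X4](=O)(=O)[#6]	1	sulfone
37	smarts	[#16X4](=O)(=O)[NX3]	1	sulfonamide
38	smarts	[#16X4](=O)(=O)[OX2]	1	sulfonate ester or acid
39	smarts	C=S	1	thiocarbonyl
40	smarts	[PX4](=O)	1	phosphoryl
41	smarts	[PX4](=O)([OX2])[OX2]	1	phosphate-like
42	smarts	[F,Cl,Br,I]	1	any halogen
43	smarts	[F,Cl,Br,I]c	1	halogen on aromatic carbon
44	smarts	[F,Cl,Br,I][CX4]	1	halogen on sp3 carbon
45	smarts	FC(F)F	1	trifluoromethyl
46	smarts	[OX2](C(F)(F)F)	1	trifluoromethoxy
47	smarts	[OX2]([#6])[#6]	1	ether
48	smarts	[OX2](c)[CH3]	1	aryl methyl ether (methoxyphenyl-like)
49	smarts	c1ccccc1	1	benzene ring
50	smarts	c1ccncc1	1	pyridine ring
51	smarts	c1cncnc1	1	pyrimidine ring
52	smarts	c1cnncc1	1	pyridazine ring
53	smarts	c1cnccn1	1	pyrazine ring
54	smarts	c1cc[nH]c1	1	pyrrole ring
55	smarts	c1ccoc1	1	furan ring
56	smarts	c1ccsc1	1	thiophene ring
57	smarts	c1c[nH]cn1	1	imidazole ring
58	smarts	c1cnco1	1	oxazole ring
59	smarts	c1cncs1	1	thiazole ring
60	smarts	c1cc[nH]n1	1	pyrazole ring
61	smarts	c1nnc[nH]1	1	triazole ring
62	smarts	c1ccc2ccccc2c1	1	naphthalene system
63	smarts	c1ccc2ncccc2c1	1	quinoline system
64	smarts	c1ccc2c(c1)cc[nH]2	1	indole system
65	smarts	c1ccc2c(c1)ncn2	1	benzimidazole-like system
66	smarts	c1ccc2c(c1)occ2	1	benzofuran system
67	smarts	c1ccc2c(c1)scc2	1	benzothiophene system
68	smarts	c1ccc2c(c1)OCO2	1	methylenedioxyphenyl
69	smarts	c1ccc(-c2ccccc2)cc1	1	biphenyl
70	smarts	[cR2]	1	fused aromatic atom
71	smarts	c1ccc2nc(N)ccc2c1	1	aminoquinoline motif
72	smarts	C1CCNCC1	1	piperidine ring
73	smarts	C1CNCCN1	1	piperazine ring
74	smarts	C1COCCN1	1	morpholine ring
75	smarts	C1CCNC1	1	pyrrolidine ring
76	smarts	C1CCOC1	1	tetrahydrofuran ring
77	smarts	C1CCOCC1	1	tetrahydropyran ring
78	smarts	C1OCCO1	1	dioxolane ring
79	smarts	N1CCSC1	1	thiazolidine ring
80	smarts	[CX4]1[CX4][CX4]1	1	cyclopropane ring
81	smarts	[#6]1[#6][#6][#6][#6][#6]1	1	six-membered carbocycle
82	smarts	[NX3]c	1	aryl amine
83	smarts	[NX3](c)[CX3]=O	1	anilide (N-aryl amide)
84	smarts	c[CX3](=O)[NX3]	1	aryl carboxamide
85	smarts	c[CX3](=O)[OX2]	1	aryl ester or acid
86	smarts	cS(=O)(=O)N	1	aryl sulfonamide
87	smarts	c[NX2]=[NX2]c	1	aromatic azo bridge
88	smarts	cOc	1	diaryl ether
89	smarts	c[CH2]c	1	methylene bridge between aromatics
90	smarts	c[CX4]	1	alkyl on aromatic ring
91	smarts	[CH3]c	1	methyl on aromatic ring
92	smarts	[$([NX3](C)(C)C)]	1	trimethylamine-like nitrogen
93	smarts	[OX1]=[CX3]	1	carbonyl oxygen
94	smarts	[#7X2]=[#6X3][#7X3]	1	amidine
95	smarts	[#6][CX3](=O)[#6]	1	dialkyl/aryl ketone
96	smarts	[CX4]([F,Cl,Br,I])([F,Cl,Br,I])	1	geminal dihalide
97	smarts	[CX4H2][OX2H]	1	primary alcohol
98	smarts	[CX4]([OX2H])([#6])[#6]	1	secondary or tertiary alcohol
99	smarts	[NX3H2]c	1	primary aryl amine (aniline)
100	smarts	n1ccc2ccccc2c1=O	1	quinolinone-like motif
101	smarts	O=c1cc[nH]c(=O)[nH]1	1	uracil-like motif
102	smarts	c1ncnc2[nH]cnc12	1	purine system
103	smarts	[#8]=[#6]1[#7][#6](=[#8])[#7][#6]1	1	hydantoin-like motif
104	smarts	C(=O)([#6])[NX3][CX4]	1	N-alkyl amide
105	smarts	[OX2][CX4][OX2]	1	acetal-like O-C-O
106	smarts	[NX3][CX4][NX3]	1	aminal-like N-C-N
107	smarts	[#6]=[#6]-[#6]=[#6]	1	conjugated diene
108	smarts	c-[CX3]=[CX3]	1	styrene-like vinyl on aromatic
109	smarts	[CX4]([#6])([#6])([#6])[#6]	1	quaternary carbon
110	smarts	[CH3][CX4H2]	1	ethyl terminus
111	smarts	[CX4H2][CX4H2][CX4H2][CX4H2]	1	butylene chain
112	smarts	[nR][cR][nR]	1	two ring nitrogens flanking a carbon (diazine motif)
113	smarts	[nX3H1]	1	protonatable aromatic NH
114	smarts	[nX2]	1	pyridine-type aromatic nitrogen
115	smarts	[OX1-,OX2H]C=O	1	carboxylate or acid
116	smarts	[NX4+]	1	quaternary ammonium
117	smarts	[O-]	1	anionic oxygen
118	smarts	[#7;R2]	1	bridgehead/fused ring nitrogen
119	smarts	[C;R][N;R][C;R](=O)	1	lactam motif
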