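no	band	gene	os_amp	os_del	rms_amp	rms_del	esft_amp	esft_del	n_sarcoma_flags	flag_os	flag_rms	flag_esft	druggable
1	7p11.2	EGFR	0.250	0.094	0.087	0.109	0.438	0.000	3	1	1	1	1
2	12q13.3	GLI1	0.156	0.375	0.891	0.000	0.313	0.188	2				0
3	2q36.1	PAX3	0.063	0.531	0.413	0.000	0.250	0.063	2				0
4	7q36.1	EZH2	0.344	0.094	0.413	0.000	0.313	0.125	2				1
5	8q24.21	MYC	0.781	0.031	0.043	0.326	0.625	0.000	2				0
6	8q24.22	LRRC6	0.625	0.031	0.391	0.043	0.625	0.063	2				0
7	8q24.13	MTSS1	0.625	0.063	0.283	0.000	0.438	0.000	2				0
8	15q11.2	MKRN3	0.219	0.188	0.065	0.109	0.438	0.125	2				0
9	11q24.2	ST3GAL4	0.156	0.281	0.174	0.130	0.438	0.125	2				0
10	15q22.2	TPM1	0.094	0.156	0.000	0.261	0.125	0.063	2				0
11	11q23.1	IL18	0.063	0.375	0.043	0.283	0.000	0.500	2				0
12	11p15.4	TRIM21	0.063	0.500	0.174	0.109	0.000	0.563	2				0
13	10q23.31	ACTA2	0.000	0.906	0.087	0.326	0.125	0.375	2				0
14	8q22.3	ODF1	0.875	0.031	0.413	0.087	0.688	0.188	1				0
15	8q24.13	SQLE	0.875	0.031	0.696	0.022	0.938	0.063	1				0
16	8q24.11	RAD21	0.781	0.031	0.304	0.022	0.625	0.063	1				0
17	8q23.3	TRPS1	0.656	0.063	0.283	0.000	0.500	0.063	1				0
18	8q21.13	PMP2	0.594	0.094	0.913	0.000	0.125	0.375	1				0
19	8q24.13	TMEM65	0.531	0.063	0.217	0.087	0.500	0.188	1				0
20	1q24.2	SELL	0.688	0.063	0.674	0.000	0.188	0.125	1				0
21	15q26.3	SNRPA1	0.688	0.125	0.000	1.000	0.125	0.188	1				0
22	22q11.21	MAPK1	0.406	0.219	0.000	0.587	0.000	0.688	1				1
23	15q26.3	IGF1R	0.313	0.094	0.130	0.065	0.125	0.000	1				0
24	15q26.1	KIF7	0.563	0.063	0.065	0.435	0.375	0.000	1				0
25	12p13.31	CD163	0.500	0.063	0.174	0.152	0.125	0.125	1				0
26	16p13.3	MAPK8IP3	0.000	0.813	0.630	0.043	0.688	0.000	1				0
27	10q22.1	NUDT13	0.000	0.781	0.739	0.000	0.125	0.438	1				0
28	10q22.1	P4HA1	0.000	0.688	0.935	0.000	0.125	0.313	1				0
29	10q23.1	TSPAN14	0.000	0.688	0.043	0.413	0.000	0.750	1				0
30	11q13.1	CFL1	0.406	0.125	1.000	0.000	0.063	0.313	1				0
31	9q22.33	ALG2	0.625	0.031	1.000	0.000	0.500	0.000	1				0
32	1q21.1	PRKAB2	0.406	0.063	1.000	0.000	0.313	0.188	1				0
33	16p11.2	ITGAL	0.063	0.375	0.978	0.000	0.375	0.250	1				0
34	7q21.2	PEX1	0.438	0.094	0.978	0.022	0.063	0.438	1				0
35	3p21.1	PRKCD	0.125	0.156	0.978	0.000	0.063	0.250	1				1
36	12q21.1	THAP2	0.344	0.219	0.978	0.000	0.438	0.063	1				0
37	19q13.33	AP2A1	0.125	0.063	0.935	0.000	0.063	0.375	1				0
38	16p11.2	ITGAM	0.031	0.406	0.913	0.000	0.063	0.250	1				0
39	10p14	KIN	0.031	0.563	0.913	0.000	0.125	0.375	1				0
40	12q15	MDM2	0.156	0.187	0.391	0.130	0.125	0.500	1				0
41	11p15.5	IGF2	0.1875	0.1875	0.283	0.0217	0.750		1				1
42	11q25	B3GAT1	0.063	0.125	0.000	1.000	0.813	0.000	1				0
43	11q13.1	PYGM	0.563	0.063	0.000	1.000	0.313	0.063	1				0
44	11q13.1	RELA	0.031	0.688	0.000	1.000	0.625	0.063	1				0
45	3p14.1	PSMD6	0.125	0.656	0.000	1.000	0.250	0.000	1				0
46	1p12	NOTCH2	0.500	0.000	0.000	1.000	0.375	0.125	1				0
47	12p13.2	ETV6	0.156	0.156	0.239	0.000	0.750	0.000	1				0
48	5q32	PDGFRB	0.063	0.531	0.065	0.870	0.750	0.000	1				1
49	7p12.3	IGFBP3	0.156	0.188	0.065	0.000	0.688	0.000	1				0
50	7p21.2	ETV1	0.156	0.063	0.152	0.000	0.563	0.000	1				0
51	7q33	CREB3L2	0.281	0.094	0.087	0.152	0.125	0.000	1				0
52	17q21.31	ETV4	0.094	0.250	0.196	0.196	0.563	0.063	1				0
53	10p11.21	ANKRD30A	0.094	0.438	0.196	0.000	0.500	0.125	1				0
54	4q12	KIT	0.219	0.063	0.000	0.130	0.375	0.000	1				1
55	12q23.2	IGF1	0.125	0.094	0.130	0.043	0.250	0.000	1				1
56	21q22.2	ERG	0.469	0.063	0.109	0.022	0.188	0.063	1				0
57	20q13.2	NFATC2	0.313	0.219	0.000	0.326	0.188	0.063	1				0
58	11q24.3	FLI1	0.156	0.125	0.043	0.348	0.188	0.125	1				0
59	xq25	STAG2	0.031	0.813	0.326	0.022	0.125	0.750	1				0
60	xp11.4	BCOR	0.000	0.938	0.130	0.217	0.438	0.563	1				0
61	17q12	TAF15	0.188	0.313	0.370	0.022	0.125	0.500	1				0
62	6p22.3	KIAA0319	0.375	0.031	0.022	0.391	0.063	0.500	1				0
63	12q13.12	ATF1	0.281	0.125	0.000	0.326	0.313	0.438	1				0
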