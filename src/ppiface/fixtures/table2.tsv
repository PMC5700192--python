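dimer_id	benchmark	nsrp	nirp	rank_svm	rank_rf	rank_lasso	rank_hier	p	distance	category	category_number
1CLV	BV4.0	12928	91	1	17	4	12	0.0070	1.52	EI	1
1FFW	BV4.0	7316	41	9	4	10	2	0.0056	2.04	OX	8
1GL1	BV4.0	7548	71	10	4	16	1	0.0094	1.25	EI	1
1H9D	BV4.0	14796	99	66	24	149	75	0.0067	1.23	OX	8
1MQ8	BV4.0	25725	59	55	787	230	242	0.0023	1.52	OX	8
1OC0	BV4.0	12456	46	194	16	18	10	0.0037	1.70	ER	3
1OYV	BV4.0	25536	105	31	5	27	13	0.0041	1.34	EI	1
1R6Q	BV4.0	10611	62	16	329	104	5	0.0058	1.42	ER	3
1SYX	BV4.0	7080	46	108	120	222	103	0.0065	2.29	OX	8
1US7	BV4.0	22184	44	96	48	874	247	0.0020	2.09	ER	3
1ZM4	BV4.0	144948	65	157	114	7	2122	0.00045	2.76	ES	2
2A5T	BV4.0	65260	73	62	110	760	155	0.0011	1.79	OX	8
2ABZ	BV4.0	16226	69	110	5	5	9	0.0043	1.30	EI	1
2G77	BV4.0	44688	94	283	19	33	151	0.0021	1.33	OG	6
2I9B	BV4.0	30360	107	140	56	24	12	0.0035	1.81	OR	7
2J0T	BV4.0	18600	71	2	55	59	198	0.0038	1.69	EI	1
2O3B	BV4.0	26875	69	16	135	29	7	0.0026	1.87	EI	1
2OUL	BV4.0	22568	93	94	18	10	1	0.0041	1.58	EI	1
2VDB	BV4.0	30672	75	145	260	380	183	0.0024	1.03	OX	8
4CPA	BV4.0	10526	56	22	43	48	14	0.0053	1.83	EI	1
2GAF	BV5.0	117448	129	66	252	8	525	0.0011	2.20	ER	3
2GTP	BV5.0	35910	59	42	125	15	6	0.0016	1.48	OG	6
2YVJ	BV5.0	36531	61	3	25	5	19	0.0017	1.90	ER	3
3A4S	BV5.0	11476	38	35	1	11	27	0.0033	2.72	EI	1
3AAD	BV5.0	37548	59	26	660	86	168	0.0016	2.14	OX	8
BAAD	BV5.0	37548	58	35	269	136	293	0.0015	1.45	OX	8
3FN1	BV5.0	16490	79	62	17	163	280	0.0048	1.24	ER	3
3K75	BV5.0	32109	54	189	2	72	300	0.0017	1.90	ER	3
3S9D	BV5.0	31408	69	69	44	112	742	0.0022	1.01	OR	7
3VLB	BV5.0	78764	96	18	604	19	11	0.0012	2.37	EI	1
4H03	BV5.0	138852	59	10	198	787	578	0.00043	2.62	ES	2
4IZ7	BV5.0	28014	44	622	213	297	1041	0.0016	1.74	EI	1
4M76	BV5.0	39772	43	74	153	434	303	0.0011	2.02	OR	7
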