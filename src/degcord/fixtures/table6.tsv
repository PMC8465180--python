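row	focal_symbol	focal_log2fc	focal_p_adj	domestic_group	wild_group	tissue	comp_symbol	comp_log2fc	comp_p_adj	source_id	provenance
1	Banp	-0.82	1e-3	rabbits	rabbits	hippocampus	Banp	-1.39	0.05	B28	table6:1
2	Banp	-0.82	1e-3	rabbits	rabbits	parietal-temporal cortex	Banp	-1.21	1e-2	B28	table6:2
3	Cd22	2.85	1e-2	dogs	wolves	blood	Cd22	2.34	0.05	B24	table6:3
4	Cd22	2.85	1e-2	foxes	foxes	pituitary	Cd22	0.32	1e-2	B23	table6:4
5	Defb17	6.02	0.05	rabbits	rabbits	parietal-temporal cortex	Defb1	1.19	1e-2	B28	table6:5
6	Eif2b3	0.63	0.05	guinea pigs	cavy	frontal cortex	Eif2b3	0.72	1e-3	B25	table6:6
7	Fcgr3a	2.06	1e-2	rabbits	rabbits	parietal-temporal cortex	Fcgr3b	1.35	1e-2	B28	table6:7
8	Fcrl2	1.12	0.05	foxes	foxes	pituitary	Fcrl1	0.43	1e-2	B23	table6:8
9	Ghitm	0.40	0.05	guinea pigs	cavy	frontal cortex	Ghitm	-0.58	0.05	B25	table6:9
10	Hbb-b1	-3.97	1e-2	dogs	wolves	blood	Hbbl	-5.92	1e-8	B24	table6:10
11	Hbb-b1	-3.97	1e-2	dogs	wolves	blood	Hba1	-4.06	1e-5	B24	table6:11
12	Hbb-b1	-3.97	1e-2	chicken	chicken	pituitary	Hbad	-1.07	1e-2	B29	table6:12
13	Hbb-b1	-3.97	1e-2	dogs	wolves	blood	Hbm	-6.46	1e-6	B24	table6:13
14	Hbb-b1	-3.97	1e-2	dogs	wolves	blood	Hbz1	-7.10	1e-2	B24	table6:14
15	Hspa1b	-1.25	0.05	rabbits	rabbits	parietal-temporal cortex	Hspa5	-1.12	0.05	B28	table6:15
16	Hspa1b	-1.25	0.05	rabbits	rabbits	amygdala	Hspa5	-1.12	0.05	B28	table6:16
17	Hspa1b	-1.25	0.05	rabbits	rabbits	parietal-temporal cortex	Hspa8	-1.46	1e-9	B28	table6:17
18	Hspa1b	-1.25	0.05	rabbits	rabbits	amygdala	Hspa8	-1.10	0.05	B28	table6:18
19	Hspa1b	-1.25	0.05	rabbits	rabbits	hippocampus	Hspa8	-1.36	1e-2	B28	table6:19
20	Ifi27l2b	2.36	0.05	chicken	chicken	pituitary	Ifi6	-2.49	1e-4	B29	table6:20
21	Krt2	-1.65	1e-4	chicken	chicken	pituitary	Krt17	-1.12	0.05	B29	table6:21
22	Liph	3.28	0.05	guinea pigs	cavy	frontal cortex	Lipa	0.84	1e-2	B25	table6:22
23	Liph	3.28	0.05	guinea pigs	cavy	frontal cortex	Lipm	1.45	1e-2	B25	table6:23
24	Liph	3.28	0.05	chicken	chicken	pituitary	Lipml	0.55	1e-3	B29	table6:24
25	Mogat2	2.08	0.05	rabbits	rabbits	hippocampus	Mogat1	-1.93	0.05	B28	table6:25
26	Morn1	1.24	1e-6	foxes	foxes	pituitary	Morn2	-0.25	0.05	B23	table6:26
27	Morn1	1.24	1e-6	guinea pigs	cavy	frontal cortex	Morn2	0.89	0.05	B25	table6:27
28	Mre11a	-2.47	1e-3	guinea pigs	cavy	frontal cortex	Mre11a	1.42	1e-4	B25	table6:28
29	Nr4a3	-1.29	1e-4	chicken	chicken	pituitary	Nr4a3	-0.85	0.05	B29	table6:29
30	Nr4a3	-1.29	1e-4	rabbits	rabbits	amygdala	Nr4a3	-1.58	0.05	B28	table6:30
31	Nr4a3	-1.29	1e-4	guinea pigs	cavy	frontal cortex	Nr2c1	-0.74	1e-2	B25	table6:31
32	Nr4a3	-1.29	1e-4	chicken	chicken	pituitary	Nr3c1	0.51	1e-5	B29	table6:32
33	Nr4a3	-1.29	1e-4	guinea pigs	cavy	frontal cortex	Nr5a1	-2.19	0.05	B25	table6:33
34	Orai1	1.83	0.05	guinea pigs	cavy	frontal cortex	Orai1	-1.30	1e-3	B25	table6:34
35	P2rx4	1.14	0.05	guinea pigs	cavy	frontal cortex	P2rx6	0.55	0.05	B25	table6:35
36	Pcdhb9	-1.01	0.05	guinea pigs	cavy	frontal cortex	Pcdh20	-0.73	0.05	B25	table6:36
37	Pcdhb9	-1.01	0.05	guinea pigs	cavy	frontal cortex	Pcdhac1	0.72	1e-2	B25	table6:37
38	Pcdhb9	-1.01	0.05	rabbits	rabbits	parietal-temporal cortex	Pcdhb15	-1.04	0.05	B28	table6:38
39	Pcdhb9	-1.01	0.05	rats	rats	frontal cortex	Pcdhga1	2.10	1e-5	B25	table6:39
40	Pcdhb9	-1.01	0.05	rabbits	rabbits	amygdala	Pcdhgb4	1.53	1e-4	B28	table6:40
41	Pcdhb9	-1.01	0.05	rabbits	rabbits	parietal-temporal cortex	Pcdhgb4	1.06	1e-4	B28	table6:41
42	Pcdhb9	-1.01	0.05	rabbits	rabbits	hypothalamus	Pcdhgb4	1.67	1e-2	B28	table6:42
43	Pla2g2c	-1.08	0.05	rabbits	rabbits	parietal-temporal cortex	Pla1a	1.35	1e-2	B28	table6:43
44	Pla2g2c	-1.08	0.05	guinea pigs	cavy	frontal cortex	Pla2g4a	-1.74	1e-7	B25	table6:44
45	Pla2g2c	-1.08	0.05	rabbits	rabbits	parietal-temporal cortex	Pla2g4c	2.29	1e-8	B28	table6:45
46	Pla2g2c	-1.08	0.05	rabbits	rabbits	amygdala	Pla2g4c	2.34	1e-3	B28	table6:46
47	Pla2g2c	-1.08	0.05	rabbits	rabbits	hippocampus	Pla2g4c	1.63	0.05	B28	table6:47
48	Pla2g2c	-1.08	0.05	guinea pigs	cavy	frontal cortex	Pla2g5	-1.01	0.05	B25	table6:48
49	Pla2g2c	-1.08	0.05	chicken	chicken	pituitary	Pla2g7	-0.83	1e-2	B29	table6:49
50	Rbm3	1.04	1e-3	guinea pigs	cavy	frontal cortex	Rbm11	1.02	0.05	B25	table6:50
51	Sh3bgr	1.11	0.05	guinea pigs	cavy	frontal cortex	Sh3bgr	0.99	1e-2	B25	table6:51
52	Shox2	6.18	0.05	rabbits	rabbits	hippocampus	Shox2	-3.43	1e-3	B28	table6:52
53	Spint1	-0.91	0.05	dogs	wolves	blood	Spint1	5.28	1e-2	B24	table6:53
54	Tpm2	1.44	1e-2	foxes	foxes	pituitary	Tpm4	0.84	1e-8	B23	table6:54
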