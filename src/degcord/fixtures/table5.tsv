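gene	group	animal_id	glove_score	rel_expr	tech_sem	provenance
Ascl3	aggressive	1	-3	0.22	0.04	table5:Ascl3:A
Ascl3	aggressive	2	-3	0.14	0.03	table5:Ascl3:A
Ascl3	aggressive	3	-3	1.04	0.12	table5:Ascl3:A
Ascl3	aggressive	4	-3	0.11	0.03	table5:Ascl3:A
Ascl3	aggressive	5	-3	0.22	0.04	table5:Ascl3:A
Ascl3	aggressive	6	-3	0.14	0.02	table5:Ascl3:A
Ascl3	aggressive	7	-3	0.12	0.03	table5:Ascl3:A
Ascl3	aggressive	8	-3	0.12	0.03	table5:Ascl3:A
Ascl3	tame	1	3	1.05	0.28	table5:Ascl3:T
Ascl3	tame	2	3	1.35	0.35	table5:Ascl3:T
Ascl3	tame	3	3	2.05	0.11	table5:Ascl3:T
Ascl3	tame	4	3	1.95	0.32	table5:Ascl3:T
Ascl3	tame	5	3	2.35	0.24	table5:Ascl3:T
Ascl3	tame	6	3	2.61	0.32	table5:Ascl3:T
Ascl3	tame	7	3	2.08	0.61	table5:Ascl3:T
Ascl3	tame	8	3	2.86	1.10	table5:Ascl3:T
Apobec1	aggressive	1	-3	1.83	0.19	table5:Apobec1:A
Apobec1	aggressive	2	-3	0.71	0.27	table5:Apobec1:A
Apobec1	aggressive	3	-3	0.30	0.08	table5:Apobec1:A
Apobec1	aggressive	4	-3	0.58	0.17	table5:Apobec1:A
Apobec1	aggressive	5	-3	0.22	0.09	table5:Apobec1:A
Apobec1	aggressive	6	-3	0.58	0.14	table5:Apobec1:A
Apobec1	aggressive	7	-3	1.86	0.28	table5:Apobec1:A
Apobec1	aggressive	8	-3	0.93	0.16	table5:Apobec1:A
Apobec1	tame	1	3	2.09	0.62	table5:Apobec1:T
Apobec1	tame	2	3	9.22	0.15	table5:Apobec1:T
Apobec1	tame	3	3	1.12	0.05	table5:Apobec1:T
Apobec1	tame	4	3	1.12	0.07	table5:Apobec1:T
Apobec1	tame	5	3	4.03	0.73	table5:Apobec1:T
Apobec1	tame	6	3	3.83	0.08	table5:Apobec1:T
Apobec1	tame	7	3	3.49	1.13	table5:Apobec1:T
Apobec1	tame	8	3	0.45	0.11	table5:Apobec1:T
Defb17	aggressive	1	-3	0.01	0.01	table5:Defb17:A
Defb17	aggressive	2	-3	0.01	0.01	table5:Defb17:A
Defb17	aggressive	3	-3	ND		table5:Defb17:A
Defb17	aggressive	4	-3	ND		table5:Defb17:A
Defb17	aggressive	5	-3	ND		table5:Defb17:A
Defb17	aggressive	6	-3	0.01	0.01	table5:Defb17:A
Defb17	aggressive	7	-3	0.01	0.01	table5:Defb17:A
Defb17	aggressive	8	-3	0.01	0.01	table5:Defb17:A
Defb17	tame	1	3	1.57	0.22	table5:Defb17:T
Defb17	tame	2	3	1.70	0.07	table5:Defb17:T
Defb17	tame	3	3	2.12	0.51	table5:Defb17:T
Defb17	tame	4	3	1.20	0.35	table5:Defb17:T
Defb17	tame	5	3	0.66	0.04	table5:Defb17:T
Defb17	tame	6	3	1.51	0.56	table5:Defb17:T
Defb17	tame	7	3	0.90	0.04	table5:Defb17:T
Defb17	tame	8	3	0.99	0.06	table5:Defb17:T
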