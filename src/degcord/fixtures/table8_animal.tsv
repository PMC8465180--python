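row	human_gene	animal_deg	log2fc	deficit_group	excess_group	source_id	provenance
1	HBD	Hbb-b1	-3.97	tame rat	aggressive rat	B75	table8:1
2	HBD	Hbbl	-5.92	dogs	wolves	B24	table8:2
3	HBD	Hba1	-4.06	dogs	wolves	B24	table8:3
4	HBD	Hbad	-1.07	domestic chicken	wild chicken	B29	table8:4
5	HBD	Hbm	-6.46	dogs	wolves	B24	table8:5
6	HBD	Hbz1	-7.10	dogs	wolves	B24	table8:6
7	NR5A1	Nr4a3	-1.29	tame rat	aggressive rat	B82	table8:7
8	NR5A1	Nr4a3	-0.85	domestic chicken	wild chicken	B29	table8:8
9	NR5A1	Nr4a3	-1.58	domestic rabbits	wild rabbits	B28	table8:9
10	NR5A1	Nr2c1	-0.74	guinea pigs	cavy	B25	table8:10
11	NR5A1	Nr3c1	0.51	wild chicken	domestic chicken	B29	table8:11
12	NR5A1	Nr5a1	-2.19	guinea pigs	cavy	B25	table8:12
13	SHOX	Shox2	6.18	aggressive rat	tame rat	B87	table8:13
14	SHOX	Shox2	-3.43	domestic rabbits	wild rabbits	B28	table8:14
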