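row	wild_species	domestic_species	tissue	n_deg	source_id	provenance
1	aggressive foxes (Vulpes vulpes)	tame foxes (V. vulpes)	pituitary	327	B23	table2:1
2	wolves (Canis familiaris)	dogs (C. lupus)	blood	450	B24	table2:2
3	wolves (C. lupus)	dogs (C. familiaris)	frontal cortex	13	B25	table2:3
4	boars (Sus scrofa)	pigs (S. scrofa)	frontal cortex	30	B25	table2:4
5	cavy (Cavia aperea)	guinea pigs (C. porcellus)	frontal cortex	883	B25	table2:5
6	wild rabbits (Oryctolagus cuniculus)	domestic rabbits (O. cuniculus domesticus)	frontal cortex	17	B25	table2:6
7	aggressive rats (R. norvegicus)	tame rats (Rattus norvegicus)	frontal cortex	20	B25	table2:7
8	boars (S. scrofa)	pigs (S. scrofa)	frontal cortex	34	B26	table2:8
9	boars (S. scrofa)	pigs (S. scrofa)	pituitary	22	B27	table2:9
10	wild rabbits (O. cuniculus)	domestic rabbits (O. cuniculus domesticus)	parietal-temporal cortex	216	B28	table2:10
11	wild rabbits (O. cuniculus)	domestic rabbits (O. cuniculus domesticus)	amygdala	118	B28	table2:11
12	wild rabbits (O. cuniculus)	domestic rabbits (O. cuniculus domesticus)	hypothalamus	43	B28	table2:12
13	wild rabbits (O. cuniculus)	domestic rabbits (O. cuniculus domesticus)	hippocampus	100	B28	table2:13
14	wild chicken (G. gallus)	domestic chicken (Gallus gallus)	pituitary	474	B29	table2:14
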