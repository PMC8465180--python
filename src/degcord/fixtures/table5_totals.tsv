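gene	group	m0	sem	provenance
Ascl3	aggressive	0.26	0.12	table5:Ascl3:A:TOTAL
Ascl3	tame	2.04	0.52	table5:Ascl3:T:TOTAL
Apobec1	aggressive	0.88	0.28	table5:Apobec1:A:TOTAL
Apobec1	tame	3.17	1.07	table5:Apobec1:T:TOTAL
Defb17	aggressive	0.01	0.01	table5:Defb17:A:TOTAL
Defb17	tame	1.33	0.35	table5:Defb17:T:TOTAL
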