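human_gene	effect_of_deficit	effect_of_excess	evidence_refs	provenance
HBD	decreased	increased	B64;B65;B66;B76	table8:HBD
NR5A1	decreased	decreased	B77;B78;B79;B80;B81	table8:NR5A1
SHOX	increased	decreased	B83;B84;B85;B86	table8:SHOX
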