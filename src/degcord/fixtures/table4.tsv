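row	symbol	name	log2fc	p_value	p_adj	provenance
1	Ascl3	achaete-scute family bHLH transcription factor 3	3.99	1e-12	1e-8	table4:1
2	Morn1	MORN repeat containing 1	1.24	1e-10	1e-6	table4:2
3	Krt2	keratin 2	-1.65	1e-8	1e-4	table4:3
4	Banp	Btg3 associated nuclear protein	-0.82	1e-6	1e-3	table4:4
5	Mre11	MRE11 homolog, double strand break repair nuclease	-2.47	1e-6	1e-3	table4:5
6	Rbm3	RNA binding motif protein 3	1.04	1e-6	1e-3	table4:6
7	Fcgr3a	Fc fragment of IgG receptor IIIa	2.06	1e-6	1e-2	table4:7
8	Plac8	placenta associated 8	2.83	1e-5	1e-2	table4:8
9	Cd22	CD22 molecule	2.85	1e-5	1e-2	table4:9
10	Apobec1	apolipoprotein B mRNA editing enzyme catalytic subunit 1	1.87	1e-5	1e-2	table4:10
11	Magee2	MAGE family member E2	-0.95	1e-5	1e-2	table4:11
12	Hbb-b1	hemoglobin, beta adult major chain	-3.97	1e-5	1e-2	table4:12
13	Tpm2	tropomyosin 2	1.44	1e-5	1e-2	table4:13
14	Apobr	apolipoprotein B receptor	1.56	1e-5	1e-2	table4:14
15	Cenps	centromere protein S	1.63	1e-4	0.05	table4:15
16	Gale	UDP-galactose-4-epimerase	1.15	1e-4	0.05	table4:16
17	Pcdhb9	protocadherin beta9	-1.01	1e-4	0.05	table4:17
18	P2rx4	purinergic receptor P2X 4	1.14	1e-4	0.05	table4:18
19	Rn45s	45S pre-ribosomal RNA	-1.62	1e-4	0.05	table4:19
20	Nr4a3	nuclear receptor subfamily 4, group A, member 3	-1.29	1e-4	0.05	table4:20
21	Ghitm	growth hormone inducible transmembrane protein	0.40	1e-4	0.05	table4:21
22	Shox2	short stature homeobox 2	6.18	1e-4	0.05	table4:22
23	Insig1	insulin induced gene 1	0.49	1e-4	0.05	table4:23
24	Orai1	ORAI calcium release-activated calcium modulator 1	1.83	1e-4	0.05	table4:24
25	Thrsp	thyroid hormone responsive	1.43	1e-4	0.05	table4:25
26	Spint1	serine peptidase inhibitor, Kunitz type 1	-0.91	1e-4	0.05	table4:26
27	Liph	lipase H	3.28	1e-4	0.05	table4:27
28	Pla2g2c	phospholipase A2, group IIC	-1.08	1e-4	0.05	table4:28
29	Lilrb3l	leukocyte immunoglobulin-like receptor, subfamily B, member 3-like	7.34	1e-4	0.05	table4:29
30	Hspa1b	heat shock protein family A (Hsp70) member 1B	-1.25	1e-4	0.05	table4:30
31	Nmral1	NmrA-like redox sensor 1	1.18	1e-4	0.05	table4:31
32	Mogat2	monoacylglycerol O-acyltransferase 2	2.08	1e-4	0.05	table4:32
33	Defb17	defensin beta 17	6.02	1e-4	0.05	table4:33
34	Sh3bgr	SH3 domain binding glutamate-rich protein	1.11	1e-4	0.05	table4:34
35	Eif2b3	eukaryotic translation initiation factor 2B subunit gamma	0.63	1e-4	0.05	table4:35
36	Fcrl2	Fc receptor-like 2	1.12	1e-4	0.05	table4:36
37	Fuca1	alpha-L-fucosidase 1	1.10	1e-4	0.05	table4:37
38	Bdh1	3-hydroxybutyrate dehydrogenase 1	0.37	1e-4	0.05	table4:38
39	Rps16	ribosomal protein S16	1.32	1e-3	0.05	table4:39
40	Ifi27l2b	interferon-alpha-inducible protein 27 like 2B	2.36	1e-3	0.05	table4:40
41	Ifi47	interferon-gamma-inducible protein 47	1.47	1e-3	0.05	table4:41
42	Mcm10	minichromosome maintenance 10 replication initiation factor	-1.98	1e-3	0.05	table4:42
43	Fjx1	four-jointed box kinase 1	0.83	1e-3	0.05	table4:43
44	Zmym6	zinc finger MYM-type containing 6	-0.59	1e-3	0.05	table4:44
45	Use1	unconventional SNARE in the ER 1	1.11	1e-3	0.05	table4:45
46	Fus	FUS RNA-binding protein	0.48	1e-3	0.05	table4:46
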