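subject_id	family_id	age_ec	ec_histology	ec_grade	ec_stage	msi	other_tumors	phenotype_override	mmr_gene	mmr_cdna	mmr_protein	ngs_ok	age_last_followup
11	D	38	endometrioid	1	1a	I			MSH2	c.244A>T	p.Lys82*	yes	
12	D	46	endometrioid	3	1b	S			MSH2	c.244A>T	p.Lys82*	yes	
16	D	38	na	na	na	na	C-29;C-43		MSH2	c.244A>T	p.Lys82*	yes	
17	E	46	endometrioid	na	na	S			MSH2	c.212-2A>G	splice	yes	
19	E	53	na	na	na	na			MSH2	c.212-2A>G	splice	yes	
26	F	49	endometrioid	1	1a	na			MSH6	c.1139_1143delATGAG	p.Asp380Alafs*6	yes	
28	F	55	endometrioid	1	1b	na			MSH6	c.1139_1143delATGAG	p.Asp380Alafs*6	yes	
18	G	44	endometrioid	1	na	I			MLH1	c.2149_2195dupl	p.His733Asnfs*66	yes	
29	G	39	na	na	na	na	O-na		MLH1	c.2149_2195dupl	p.His733Asnfs*66	yes	
2	A	52	endometrioid	2	1b	S			MSH6	c.3729_3732dupATTA	p.Phe1245Ilefs*31	yes	
3	A	65	serous	3	1c	I	C-59		MSH6	c.3729_3732dupATTA	p.Phe1245Ilefs*31	yes	
6	B	51	endometrioid	1	1b	S			MSH6	c.3729_3732dupATTA	p.Phe1245Ilefs*31	yes	
7	B	62	endometrioid	3	2	I	C-70;U-81		MSH6	c.3729_3732dupATTA	p.Phe1245Ilefs*31	yes	
8	C	54	endometrioid	1	1a	I			MSH6	c.3729_3732dupATTA	p.Phe1245Ilefs*31	yes	
9	C	52	endometrioid	1	1	S	B-na		MSH6	c.3729_3732dupATTA	p.Phe1245Ilefs*31	yes	
1	-	50	endometrioid	1	2	I			MSH6	c.3729_3732dupATTA	p.Phe1245Ilefs*31	yes	
4	-	57	endometrioid	3	na	I			MSH6	c.3729_3732dupATTA	p.Phe1245Ilefs*31	yes	
5	-	62	endometrioid	1	1b	I			MSH6	c.3729_3732dupATTA	p.Phe1245Ilefs*31	yes	
10	-	40	endometrioid	1	na	na	O-40		MSH6	c.1444C>T	p.Arg482*	yes	
13	-	81	na	na	na	na	C-59		PMS2	c.989-296_1144+706del	p.Glu330_Glu381del	yes	
14	-	31	na	na	na	na			MSH6	c.3772C>T	p.Gln1258*	yes	
15	-	49	endometrioid	1	3	S	O-49		MSH6	c.2569_2572del	p.Asp857Phefs10*	yes	
20	-	56	endometrioid	na	na	S	B-50		MSH6	c.2191C>T	p.Gln731*	yes	
21	-	58	endometrioid	1	1b	I	C-58		MLH1	c.901C>T	p.Gln301*	yes	
22	-	60	endometrioid	1	3	na			MSH6	c.2815C>T	p.Gln939*	no	
23	-	49	endometrioid	1	1b	I			PMS2	c.24-12_107del96	p.Ser8Argfs5*	yes	
24	-	61	endometrioid	3	1b	I	C-56		MSH6	c.4002-22_4002-4del19	splice	yes	
25	-	44	endometrioid	1	na	I			MSH6	c.3838C>T	p.Gln1280*	no	
27	-	40	na	na	na	S			MSH2	c.212-?_366+?del	p.Ala72Phefs*9	yes	
30	-	71	endometrioid	2	3	I			MSH2	c.646-2A>G	splice	yes	
31	-	50	mixed	3	1b	I			MSH6	c.2191C>T	p.Gln731*	yes	
32	-	64	endometrioid	1	1a	S			MSH6	c.2926_2929dupCGTT	p.Tyr977Serfs*8	yes	
33	-	49	endometrioid	1	1b	I			MSH6	c.1804_1805del2	p.Ser602Lysfs*4	yes	
34	-	75	endometrioid	1	1b	na	C-na		MSH6	c.3794_3801del8	p.His1266Metfs*6	yes	
35	-	64	endometrioid	1	1b	I			MSH6	c.3949_3965del17	p.His1317Ilefs*2	yes	
37	-	53	na	na	na	na	C-52		MSH2	c.1203dup	p.Gln402Thrfs*15	yes	
38	-	55	endometrioid	2	1	I			MSH6	c.3185G>T	p.Cys1062Phe	yes	
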