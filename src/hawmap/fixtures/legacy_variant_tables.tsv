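strain	gene	mutation	description	causal
emb-6(g36ts)	tyms-1	G->A, Gly42Arg	Thymidylate synthase ortholog	1
emb-6(g36ts)	npp-6	G->A, Gly861Arg	Nuclear pore complex	0
emb-6(g36ts)	frm-4	C->T, Pro241Ser	FERM domain protein	0
emb-6(g36ts)	lpd-2	G->A, Ala14Thr	Lipid depleted	0
emb-6(g36ts)	crml-1	C->T, Ser66Leu	Capping, ARp2/3, Myosin I linker protein	0
emb-6(g36ts)	T28F4.3	C->T, Ser116Phe	No information available	0
emb-6(g36ts)	F27D4.6	G->A, Arg980Lys	No information available	0
emb-6(g36ts)	smgl-1	C->T, Pro698Ser	SMG-associated and lethal	0
emb-17(g20ts)	lpd-3	C->T, Ala467Thr	Lipid depleted	0
emb-17(g20ts)	met-1	C->T, Arg1167Cys	Histone methyltransferase	0
emb-17(g20ts)	M04F3.2	G->T, Glu17stop	No information available	0
emb-17(g20ts)	rab-10	C->T, Ala82Thr	Rab-like GTPase	0
emb-17(g20ts)	ekl-1	C->A, Leu582Ile	Enhancer of Ksr-1 Lethality	0
emb-17(g20ts)	rde-2	G->T, Thr148Asn	RNAi defective	0
emb-17(g20ts)	smgl-1	C->T, Asp1141Asn	SMG-associated and lethal	0
emb-17(g20ts)	F55H12.4	T->C, Lys170Arg	No information available	0
emb-17(g20ts)	chaf-1	C->T, Arg436His	Chromatin Assembly Factor	1
emb-17(g20ts)	B0205.1	C->T, Ser268Asn	No information available	0
emb-10(k12ts)	mus-101	G->A, Cys268Tyr	Chromosomal protein for DNA metabolic processes	1
emb-10(k12ts)	F59C6.8	C->T, Thr446Met	No information available	0
zyg-2(b10ts)	mus-101	G->A, Trp1062stop	Chromosomal protein for DNA metabolic processes	1
zyg-2(b10ts)	lrk-1	G->A, Gly1244Asp	Leucine-rich repeat kinase	0
mel-2(it20)	tofu-6	C->T, Gln52stop	SRA stem-loop interacting RNA binding protein	1
mel-2(it20)	cyp-4	C->T, Thr157Ile	Cyclophilin divergent member	0
mel-2(it20)	C25H3.8	G->A, Ser281Asn	No information available	0
mel-2(it20)	C56C10.10	G->A, Arg118Gln	No information available	0
mel-2(it20)	T14B4.2	A->C, Asn94His	No information available	0
mel-2(it20)	T14B4.2	A->C, Lys95Gln	No information available	0
mel-2(it20)	F41G3.20	Insertion of a C between nucleotide 207 and 208; frameshift	No information available	0
emb-14(g43ts)	pqn-20	C->T, Ser51Phe	Prion-like-(Q/N-rich)-domain-bearing protein	0
emb-14(g43ts)	syp-4	C->T, Thr354Ile	Synapsis in meiosis abnormal	0
emb-14(g43ts)	T21G5.1	C->A, Pro144Gln	No information available	0
emb-14(g43ts)	smg-1	G->A, Trp652stop	Phosphatidylinositol kinase-related protein kinase	0
emb-14(g43ts)	lrp-1	C->T, Pro645Leu	low-density lipoprotein (LDL) receptor-like protein	0
emb-14(g43ts)	F26A3.1	G->A, Glu276Lys	No information available	0
emb-14(g43ts)	fasn-1	G->A, Ala1425Thr	Fatty acid synthase	1
emb-29(g52ts)	nas-32	G->A, Ala77Thr	Astacin family zinc metalloprotease	0
emb-29(g52ts)	cdc-25.2	C->T, Ser239Phe	Cdc25 phosphatase protein family homolog	1
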