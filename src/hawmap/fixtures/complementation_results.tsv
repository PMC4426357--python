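strain	partner_allele	temperature	percent_hatching	n	printed_verdict	sterility_note
emb-6(g36ts)	tyms-1(tm2429)	24	0	16	fails
emb-6(g36ts)	npp-6(ok2821)	24	94	14	complements
emb-6(g36ts)	smgl-1(ok2423)	24	95	8	complements
emb-17(g20ts)	lpd-3(ok2138)	24	98	10	complements
emb-17(g20ts)	ekl-1(ok1197)	24	97	9	complements
emb-17(g20ts)	smgl-1(ok2423)	24	87	5	complements
emb-17(g20ts)	chaf-1(n5453)	24	4.9	46	fails
emb-10(k12ts)	mus-101(tm1761)	24	1	12	fails
zyg-2(b10ts)	mus-101(tm1761)	24	0	9	fails
emb-14(g43ts)	syp-4(tm2713)	24	81	9	complements
emb-29(g52ts)	cdc-25.2(ok597)	24	78.6	20	complements	91% of F2s are sterile (N=34)
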