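# Synthetic example brood counts (hand-written demonstration data, not measurements).
# Columns: genotype, temperature (C), eggs laid, larvae hatched, replicate id.
genotype	temperature	eggs_laid	hatched	replicate
wildtype	15	210	208	1
wildtype	15	195	193	1
wildtype	15	188	187	2
wildtype	15	224	221	2
wildtype	15	201	200	3
wildtype	15	217	215	3
wildtype	24	190	188	1
wildtype	24	205	203	1
wildtype	24	182	180	2
wildtype	24	199	198	2
wildtype	24	208	206	3
wildtype	24	186	184	3
ts-mutant	15	176	170	1
ts-mutant	15	182	175	1
ts-mutant	15	168	159	2
ts-mutant	15	190	181	2
ts-mutant	15	174	168	3
ts-mutant	15	180	172	3
ts-mutant	24	165	1	1
ts-mutant	24	158	0	1
ts-mutant	24	171	2	2
ts-mutant	24	149	0	2
ts-mutant	24	162	1	3
ts-mutant	24	177	0	3
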