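snp	gene	arm	low_genotypes	high_genotypes	n_low	n_high	mean_low	sd_low	mean_high	sd_high	p_value
rs2605100	LYPLAL1	MHP	GG	AA+AG	47	49	-4.9	2.7	-3.8	2.8	0.050
rs3123554	CNR2	MHP	AA+AG	GG	71	25	-4.7	2.9	-3.5	2.2	0.080
rs1801282	PPARG	MHP	CG	CC	12	84	-5.7	3.7	-4.2	2.6	0.075
rs7903146	TCF7L2	MHP	TT	CC+CT	16	80	-5.6	2.4	-4.1	2.8	0.049
rs12255372	TCF7L2	MHP	GT+TT	GG	65	31	-4.7	2.9	-3.7	2.5	0.089
rs6265	BDNF	MHP	CT+TT	CC	33	63	-5.3	3.2	-3.9	2.5	0.023
rs11030104	BDNF	MHP	AG+GG	AA	37	59	-5.2	3.1	-3.8	2.4	0.013
rs10767664	BDNF	MHP	TA	TT+AA	29	67	-5.7	3.3	-3.8	2.4	0.002
rs659366	UCP2	MHP	CC	CT+TT	48	48	-4.9	3.0	-3.8	2.5	0.071
rs2734827	UCP3	MHP	GG	GA+AA	46	50	-4.9	3.0	-3.8	2.5	0.056
rs3813929	HTR2C	MHP	CC+TT	CT	80	16	-4.6	2.8	-3.1	2.6	0.041
rs484066	ABCB11	LF	TT	AA+AT	49	56	-4.8	3.0	-3.9	2.3	0.099
rs660339	UCP2	LF	GA	GG+AA	54	51	-4.8	2.7	-3.7	2.5	0.024
rs1805081	NPC1	LF	TT+TC	CC	87	18	-4.5	2.8	-3.2	1.6	0.095
rs17069904	TNFRSF11A	LF	GA+AA	GG	19	86	-5.5	3.5	-4.0	2.4	0.053
rs2287019	QPCTL	LF	CT	CC+TT	30	75	-4.8	2.7	-4.1	2.6	0.086
rs3813929	HTR2C	LF	CC+TT	CT	87	18	-4.7	2.7	-2.6	1.7	0.007
rs11091046	AGTR2	LF	AA+CC	AC	60	45	-5.0	2.8	-3.4	2.2	0.003
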