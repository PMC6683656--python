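snp	gene	arm	low_genotypes	high_genotypes	n_low	n_high	mean_low	sd_low	mean_high	sd_high	p_value
rs2605100	LYPLAL1	MHP	GG	AA+AG	47	49	-9.8	3.9	-8.0	4.9	0.046
rs662799	APOA5	MHP	AA	GA	83	13	-9.2	4.1	-6.8	6.4	0.067
rs1685325	UCP3	MHP	TC+CC	TT	70	26	-9.4	4.4	-7.5	4.3	0.055
rs1558902	FTO	MHP	AA	TT+TA	16	80	-10.8	4.9	-8.5	4.3	0.067
rs1121980	FTO	MHP	GG+AA	GA	61	35	-9.7	4.5	-7.4	4.2	0.014
rs3813929	HTR2C	MHP	CC+TT	CT	80	16	-9.4	4.5	-6.1	3.2	0.007
rs10838738	MTCH2	LF	AA	AG+GG	39	66	-10.7	4.6	-8.8	3.8	0.028
rs17069904	TNFRSF11A	LF	GA+AA	GG	19	86	-11.6	5.1	-9.1	3.9	0.017
rs11091046	AGTR2	LF	AA	AC+CC	27	78	-11.6	4.8	-8.8	3.8	0.004
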