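outcome	arm	n_loci	ugrs_min	ugrs_max	wgrs_min	wgrs_max	corrected_adj_r2
WCR	MHP	6	0	6	-1.43	11.68	0.2081
WCR	LF	3	0	3	0	6.83	0.2208
TFATL	MHP	11	0	11	1.05	8.17	0.3208
TFATL	LF	7	0	7	0	7.51	0.3792
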