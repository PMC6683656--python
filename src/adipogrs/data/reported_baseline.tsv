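variable	mhp_mean	mhp_sd	lf_mean	lf_sd	p_value
n	96		105
weight_kg	86.8	13.9	88.8	12.2	0.288
bmi	31.2	3.1	32.2	3.7	0.052
baseline_tfat	41.9	5.5	41.9	6.7	0.991
vfat_kg	1.39	0.86	1.46	0.81	0.551
baseline_wc	101.7	10.7	102.8	9.8	0.445
sbp	129.4	19.6	128.1	16.1	0.620
dbp	78.7	11.1	80.0	10.8	0.404
glucose	95.4	9.7	95.8	10.9	0.775
tc	214.6	37.4	217.8	39.9	0.547
hdl	54.1	12.7	56.2	13.3	0.252
tg	100.7	51.6	103.0	57.9	0.768
tyg	4.53	0.24	4.54	0.25	0.833
energy	2933	778	3032	1029	0.447
carbohydrate_pct	40.2	6.5	40.8	6.6	0.528
protein_pct	16.7	2.7	17.0	3.0	0.471
fat_pct	41.2	6.0	40.2	5.7	0.239
mets	23.7	20.0	24.6	18.2	0.740
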