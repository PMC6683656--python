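variable	mhp_mean	mhp_sem	lf_mean	lf_sem	p_value
TFATL	-4.4	0.3	-4.3	0.3	0.852
WCR	-8.9	0.5	-9.7	0.5	0.231
delta_weight_kg	-8.5	0.4	-9.1	0.4	0.235
delta_bmi	-3.1	0.1	-3.3	0.1	0.253
delta_vfat_kg	-0.5	0.03	-0.5	0.02	0.502
delta_sbp	-12.4	1.2	-10.9	1.1	0.370
delta_dbp	-4.2	1.0	-4.5	1.0	0.856
delta_glucose	-4.2	0.8	-4.5	0.8	0.768
delta_tc	-18.2	2.6	-22.7	2.5	0.210
delta_hdl	-3.0	0.8	-5.1	0.7	0.052
delta_tg	-19.2	3.7	-14.2	3.6	0.331
delta_tyg	-0.12	0.19	-0.09	0.18	0.231
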