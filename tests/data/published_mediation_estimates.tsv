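mediator	outcome	total_effect	direct_effect	indirect_effect	proportion_pct	proportion_lo_pct	proportion_hi_pct	additivity_exact
SBP	CKD	0.17	0.16	0.01	4.62	-0.48	9.71	1
SBP	kidney_failure	0.20	0.19	0.01	3.85	0.08	7.62	1
SBP	dialysis	0.23	0.22	0.01	5.46	1.72	9.21	1
T2DM	CKD	0.17	0.10	0.07	43.24	26.36	60.11	1
T2DM	kidney_failure	0.20	0.13	0.06	32.47	19.96	44.98	0
T2DM	dialysis	0.23	0.20	0.03	14.33	7.32	21.34	1
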