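patient	histology	n_intervals	test_retest	ilae_outcome	followup_months	morphology_label	snn_label
1	HS	28	0.95	1	12	TN	TN
2	Glioma	13	0.97	1	29	TN	TN
3	HS	39	0.83	1	13	TN	TN
4	HS	34	0.96	1	41	TN	TN
5	HS	35	0.91	1	14	TN	TN
6	HS	35	0.59	1	11	TN	TN
7	HS	1		3	42	FN	FN
8	HS	16	0.74	3	15	FN	TP
9	HS	12	0.90	5	46	FN	FN
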