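stratum	total	oa	hv	females	females_oa	females_hv	p_sex	age_mean	age_sd	age_oa_mean	age_oa_sd	age_hv_mean	age_hv_sd	p_age	bmi_mean	bmi_sd	bmi_oa_mean	bmi_oa_sd	bmi_hv_mean	bmi_hv_sd	p_bmi
all	346	152	194	187	77	110	0.312	56.1	12.8	63.8	7.5	50.0	12.8	<0.001	30.0	5.4	31.8	5.6	28.6	4.9	<0.001
males	159	75	84					57.3	12.1	63.6	7.9	51.7	12.4	<0.001	29.7	4.7	31.1	4.9	28.5	4.2	<0.001
females	187	77	110					55.0	13.3	64.1	7.1	48.7	12.9	<0.001	30.3	6.0	32.5	6.1	28.7	5.4	<0.001
bmi_ge_30	172	89	83	98	47	51	0.323	56.0	12.1	62.9	5.9	48.5	12.7	<0.001	34.0	4.2	35.0	5.0	33.0	2.7	0.002
bmi_lt_30	174	63	111	89	30	59	0.586	56.2	13.4	65.2	9.1	51.1	12.8	<0.001	26.0	3.2	27.4	2.4	25.3	3.3	<0.001
age_gt_50	250	148	102	128	76	52	1.000	62.5	6.9	64.4	6.7	59.9	6.2	<0.001	30.7	5.2	32.0	5.5	28.8	3.8	<0.001
males_age_gt_50	122	72	50					62.6	7.0	64.5	6.5	59.8	6.8	<0.001	30.3	4.4	31.2	4.9	29.1	3.0	0.005
females_age_gt_50	128	76	52					62.5	6.7	64.3	6.9	59.9	5.6	<0.001	31.0	5.8	32.7	6.0	28.5	4.5	<0.001
age_gt_50_bmi_ge_30	131	89	42	70	47	23	0.983	61.5	6.5	62.9	5.9	58.6	6.7	0.001	34.1	4.4	35.0	5.0	32.2	2.1	<0.001
age_gt_50_bmi_lt_30	119	59	60	58	29	29	1.000	63.7	7.1	66.6	7.2	60.8	5.7	<0.001	26.9	2.6	27.4	2.3	26.4	2.8	0.031
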