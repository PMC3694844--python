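probe_id	gene	location	meth_before_mean	meth_before_sd	meth_after_mean	meth_after_sd	meth_difference	meth_p	meth_q	cross_reactive_bases	expr_before_mean	expr_before_sd	expr_after_mean	expr_after_sd	expr_difference	expr_p	expr_q
cg05501868	ADAMTS9	Body	62.3	4.1	66.5	4.5	4.1	6e-4	0.025	0	218.5	46.5	219.7	59.8	1.3
cg21527616	ADAMTS9	Body	63.6	4.7	67.0	3.3	3.4	1e-3	0.044	0	218.5	46.5	219.7	59.8	1.3
cg14567877	ADCY5	Body	80.7	4.3	84.2	3.8	3.5	2e-4	0.015	0	257.2	48.3	253.1	44.8	-4.1
cg03720898	ARAP1	Body	73.7	3.7	77.1	2.3	3.4	9e-5	0.013	48	209.4	35.0	202.8	36.4	-6.6
cg06838038	ARAP1	Body	42.4	3.9	46.1	3.6	3.7	4e-5	0.011	0	209.4	35.0	202.8	36.4	-6.6
cg10495997	ARAP1	5UTR; S Shore	61.8	3.2	64.0	2.9	2.2	2e-4	0.015	0	209.4	35.0	202.8	36.4	-6.6
cg15279866	ARAP1	5UTR; Body	56.4	3.5	58.8	3.9	2.4	1e-3	0.042	0	209.4	35.0	202.8	36.4	-6.6
cg27058763	ARAP1	Body; S Shelf	57.1	4.0	60.7	3.3	3.5	1e-3	0.041	0	209.4	35.0	202.8	36.4	-6.6
cg01865786	BCL11A	Body	64.7	4.3	67.7	2.8	3.0	8e-4	0.034	0	19.4	2.1	21.3	2.7	1.8	0.009	0.04
cg03390300	CDKAL1	Body	85.2	2.3	87.5	1.8	2.4	2e-5	0.011	0	263.1	24.7	268.3	25.1	5.2
cg07562918	CDKN2A	1stExon; CpG Island	16.7	2.1	18.4	2.2	1.6	1e-3	0.042	0	35.9	5.3	40.5	7.0	4.6	0.023	0.09
cg20836993	DGKB	Body	68.3	1.8	70.0	1.7	1.7	6e-4	0.025	48	16.8	3.5	17.8	3.9	0.9
cg01602287	DUSP8	Body; CpG Island	75.4	4.5	79.5	3.4	4.2	1e-3	0.042	0	97.7	13.9	94.9	13.5	-2.9
cg26902557	DUSP8	Body	49.1	3.9	52.1	4.0	3.0	6e-4	0.028	0	97.7	13.9	94.9	13.5	-2.9
cg26580413	FTO	Body	61.0	4.4	64.3	3.8	3.3	1e-3	0.044	0	785.0	80.7	794.4	64.7	9.4
cg20180364	HHEX	TSS1500; N Shore	46.8	4.1	50.4	3.5	3.6	2e-4	0.015	0	172.7	24.7	144.9	30.3	-27.8	5e-5	0.001
cg16965605	HMGA2	Body	70.2	5.6	75.1	4.3	4.9	1e-3	0.037	0	32.2	3.2	34.9	3.6	2.7	0.004	0.025
cg17182048	HMGA2	Body	81.2	3.9	84.5	4.8	3.4	1e-3	0.044	0	32.2	3.2	34.9	3.6	2.7	0.004	0.025
cg17518348	HMGA2	Body	78.8	3.7	83.3	3.5	4.5	2e-4	0.015	0	32.2	3.2	34.9	3.6	2.7	0.004	0.025
cg06150454	IGF2BP2	Body	54.6	4.2	58.4	2.8	3.8	3e-4	0.021	48	105.6	16.5	88.4	14.9	-17.1	1e-5	0.001
cg13918631	IGF2BP2	Body	66.8	4.7	70.7	3.8	3.9	2e-4	0.015	0	105.6	16.5	88.4	14.9	-17.1	1e-5	0.001
cg02963803	JAZF1	Body	59.6	2.6	62.1	2.5	2.5	9e-5	0.013	48	238.2	26.1	218.5	28.0	-19.7	0.01	0.047
cg01689159	KCNQ1	Body; CpG Island	80.5	2.6	83.3	1.7	2.7	3e-4	0.017	0	67.0	7.0	66.1	7.4	-0.9
cg03660952	KCNQ1	Body	51.8	3.5	55.0	2.6	3.2	1e-5	0.011	0	67.0	7.0	66.1	7.4	-0.9
cg04894537	KCNQ1	Body	40.5	3.5	44.6	4.3	4.2	3e-4	0.021	0	67.0	7.0	66.1	7.4	-0.9
cg06838584	KCNQ1	Body	46.8	3.7	44.0	3.4	-2.7	2e-4	0.015	0	67.0	7.0	66.1	7.4	-0.9
cg08160246	KCNQ1	Body	60.3	3.3	63.5	3.3	3.2	5e-4	0.025	0	67.0	7.0	66.1	7.4	-0.9
cg13577072	KCNQ1	Body	67.4	3.1	71.8	3.5	4.5	6e-5	0.011	0	67.0	7.0	66.1	7.4	-0.9
cg15910264	KCNQ1	Body	81.4	2.8	84.3	1.9	2.9	3e-5	0.011	0	67.0	7.0	66.1	7.4	-0.9
cg19672982	KCNQ1	Body	70.4	3.0	73.3	2.8	2.9	1e-4	0.014	0	67.0	7.0	66.1	7.4	-0.9
cg24725201	KCNQ1	Body	91.9	1.6	93.4	1.4	1.5	7e-4	0.031	0	67.0	7.0	66.1	7.4	-0.9
cg25786675	KCNQ1	Body	66.3	3.7	62.4	3.6	-3.9	6e-5	0.011	0	67.0	7.0	66.1	7.4	-0.9
cg04775232	PRC1	Body	82.1	2.4	84.0	2.2	1.9	2e-3	0.048	0	64.3	12.0	59.8	15.8	-4.5
cg01902845	PROX1	Body	73.5	5.0	77.7	3.4	4.2	6e-4	0.025	0	21.2	6.2	21.2	7.0	0
cg14545834	PTPRD	Body; CpG Island	68.0	2.8	71.2	2.2	3.2	2e-4	0.015	49	80.3	17.8	81.8	14.5	1.4
cg00831931	TCF7L2	Body	82.4	2.7	84.8	2.5	2.4	2e-4	0.015	0	529.9	58.9	474.0	74.7	-55.8	0.001	0.008
cg05923857	TCF7L2	Body	72.6	5.2	76.4	3.8	3.8	8e-4	0.034	0	529.9	58.9	474.0	74.7	-55.8	0.001	0.008
cg06403317	TCF7L2	Body	92.1	2.6	94.2	1.7	2.1	1e-3	0.037	0	529.9	58.9	474.0	74.7	-55.8	0.001	0.008
cg09022607	TCF7L2	Body; S Shore	25.5	4.5	21.2	3.1	-4.3	6e-4	0.025	0	529.9	58.9	474.0	74.7	-55.8	0.001	0.008
cg19226647	TCF7L2	1stExon; N Shore	4.4	1.0	5.5	1.3	1.1	4e-5	0.011	0	529.9	58.9	474.0	74.7	-55.8	0.001	0.008
cg23951816	TCF7L2	Body	63.8	3.8	68.4	3.5	4.6	5e-4	0.025	0	529.9	58.9	474.0	74.7	-55.8	0.001	0.008
cg01649611	THADA	Body	38.5	5.3	42.5	4.6	4.0	2e-4	0.015	0	285.2	29.9	291.7	31.4	6.5
cg12277798	THADA	Body; S Shelf	77.2	4.4	81.6	3.3	4.5	5e-4	0.025	0	285.2	29.9	291.7	31.4	6.5
cg16417416	WFS1	Body	63.9	3.5	66.9	2.9	2.9	1e-3	0.044	0	132.2	21.6	123.6	14.5	-8.6	0.036	0.13
cg22051204	ZBED3	5UTR; S Shore	51.1	3.5	53.5	3.2	2.4	1e-3	0.042	0	187.9	22.9	189.1	17.4	1.3
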