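probe_id	gene	location	meth_before_mean	meth_before_sd	meth_after_mean	meth_after_sd	meth_difference	meth_p	meth_q	cross_reactive_bases	expr_before_mean	expr_before_sd	expr_after_mean	expr_after_sd	expr_difference	expr_p	expr_q
cg05501868	ADAMTS9	Body	62.3	4.1	66.5	4.5	4.1	6e-4	0.039	0	218.5	46.5	219.7	59.8	1.3
cg07233933	CPEB4	Body	76.9	2.1	79.2	1.7	2.3	1e-4	0.013	0	377.9	63.9	319.3	51.1	-58.7	1e-5	0.002
cg09141413	GPRC5B	TSS200; CpG Island	15.9	2.4	13.7	1.8	-2.2	6e-4	0.039	0	476.3	69.3	448.5	58.4	-27.8
cg22380033	GRB14	1stExon; 5UTR; CpG Island	2.1	0.4	2.6	0.4	0.5	3e-4	0.029	0	65.1	11.4	63.0	16.8	-2.1
cg07645296	ITPR2	TSS1500; S Shore	56.2	4.5	60.1	4.6	3.9	1e-4	0.013	0	421.5	63.1	401.6	91.0	-19.9
cg13203394	ITPR2	Body	56.8	4.4	63.3	3.2	6.5	5e-7	0.001	0	421.5	63.1	401.6	91.0	-19.9
cg02212836	LY86	1stExon	40.0	2.4	42.7	2.5	2.7	9e-5	0.013	0	44.2	17.0	57.8	41.0	13.6
cg05021589	LY86	TSS200	39.7	2.9	43.5	3.0	3.7	3e-5	0.013	0	44.2	17.0	57.8	41.0	13.6
cg09249494	LY86	TSS200	31.4	3.9	35.2	3.4	3.9	1e-4	0.013	0	44.2	17.0	57.8	41.0	13.6
cg16681597	LYPLAL1	Body; CpG Island	9.6	1.6	11.1	2.1	1.6	5e-4	0.038	0	146.7	34.7	165.0	28.7	18.3	0.019	0.08
cg01362115	MAP2K5	Body	76.3	2.4	78.2	2.1	2.0	7e-4	0.043	0	205.2	23.8	195.0	24.6	-10.2
cg02328326	MAP2K5	Body	79.6	5.8	84.8	3.8	5.2	6e-4	0.043	0	205.2	23.8	195.0	24.6	-10.2
cg20055861	MAP2K5	Body	67.4	3.9	71.9	2.9	4.5	1e-4	0.013	0	205.2	23.8	195.0	24.6	-10.2
cg27519910	MSRA	Body; S Shelf	76.0	2.3	78.6	2.3	2.7	4e-5	0.013	48	120.4	12.5	124.0	13.5	3.6
cg20147645	MTIF3	5UTR; N Shore	60.0	3.3	64.1	3.6	4.0	3e-4	0.024	0	331.3	42.3	331.7	39.8	0.4
cg16420308	NRXN3	Body; N Shore	87.3	2.4	89.5	1.7	2.3	7e-4	0.043	0	34.4	4.1	34.7	5.4	0.3
cg16592301	PRKD1	Body	84.0	2.7	86.3	2.4	2.3	8e-4	0.048	0	182.1	20.5	177.4	28.0	-4.7
cg16104450	SDCCAG8	Body; N Shore	40.5	3.9	44.2	3.6	3.7	1e-4	0.013	0	258.8	22.1	234.9	32.9	-23.9	1e-3	0.008
cg08222913	STAB1	Body; CpG Island	63.2	5.1	67.8	4.2	4.6	2e-5	0.013	0	224.1	56.3	214.6	44.2	-9.6
cg26104752	TBX15	5UTR; S Shore	5.8	1.4	6.8	1.5	1.0	7e-5	0.013	0	374.1	37.2	368.1	50.9	-6.0
cg19694781	TMEM160	Body; N Shore	56.1	6.5	58.3	7.0	2.3	1e-4	0.013	48	205.0	25.6	231.1	25.7	26.1	1e-3	0.008
cg05003666	TUB	TSS200;Body;CpG Island	21.8	2.5	18.4	2.3	-3.4	3e-4	0.029	0	73.6	6.7	72.7	8.0	-0.9
cg01610165	ZNF608	Body	10.5	2.3	13.1	2.3	2.6	7e-4	0.043	0	171.2	22.9	162.7	25.1	-8.5
cg12817840	ZNF608	Body	21.8	2.5	25.8	3.8	3.9	9e-5	0.013	0	171.2	22.9	162.7	25.1	-8.5
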