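probe_id	chromosome	gene	gene_regions	island_relation	before_mean	before_sd	after_mean	after_sd	difference	p_value	q_value	cross_reactive_bases
cg06550177	7		Intergenic	S_Shore	29.6	7.2	40.6	7.8	10.9	1.67e-5	0.008	0
cg13906823	1	TSTD1	TSS200	Island	39.2	12.5	50.1	15.6	10.9	4.03e-5	0.011	0
cg23397147	17		Intergenic	OpenSea	48.1	11.0	58.9	7.5	10.8	4.75e-4	0.028	0
cg24161057	1	TSTD1	TSS200	Island	35.9	13.5	46.6	14.6	10.7	2.10e-5	0.009	0
cg26155520	1		Intergenic	OpenSea	55.6	7.1	66.0	6.6	10.4	7.87e-6	0.007	0
cg05874882	4		Intergenic	N_Shore	34.0	9.1	44.2	6.7	10.1	6.03e-5	0.013	0
cg00257920	1		Intergenic	S_Shelf	47.5	9.7	57.5	7.7	10.0	1.53e-4	0.018	0
cg03878654	16	ZFHX3	5UTR	N_Shore	56.6	6.7	65.9	6.9	9.3	1.81e-4	0.019	0
cg08360726	19	PLD3	5UTR	Island	29.7	8.0	38.9	11.8	9.2	1.28e-3	0.043	0
cg26682335	17	ABR	Body	OpenSea	60.6	9.4	69.7	7.0	9.1	2.53e-4	0.022	0
cg01425666	7		Intergenic	Island	33.3	6.8	42.3	5.7	9.0	2.62e-5	0.010	0
cg01750221	12		Intergenic	OpenSea	52.3	7.5	61.1	6.4	8.8	8.49e-4	0.036	0
cg05455393	X	FHL1	TSS1500	N_Shore	52.5	8.4	61.1	7.2	8.6	1.28e-4	0.017	0
cg22828884	3	FOXP1	Body	OpenSea	62.6	4.4	71.2	4.3	8.6	1.67e-5	0.008	0
cg11837417	19	CLDND2	TSS1500	S_Shore	65.3	6.4	73.9	5.2	8.6	4.08e-4	0.027	0
cg10323490	2	THNSL2	TSS1500	N_Shore	64.1	8.1	72.6	6.2	8.5	9.76e-4	0.038	0
cg03934443	10		Intergenic	OpenSea	67.4	11.8	75.8	5.6	8.4	9.76e-4	0.038	0
cg01775802	14	RGS6	Body	OpenSea	63.2	10.1	71.4	10.9	8.2	9.76e-4	0.038	0
cg24606240	1	NUCKS1	TSS1500	S_Shore	55.4	7.9	63.6	5.9	8.2	7.38e-4	0.034	0
cg23499846	17	KIAA0664	5UTR	S_Shore	54.0	5.9	62.0	4.3	8.0	1.03e-5	0.007	0
cg21821308	2	ASAP2	Body	Island	42.0	8.5	33.8	5.9	-8.1	3.49e-4	0.025	0
cg19219423	10	PRKG1	Body	OpenSea	55.4	7.7	47.1	6.8	-8.3	1.81e-4	0.019	0
cg03862437	3	TMEM44	Body	N_Shore	46.3	7.0	38.0	5.2	-8.3	5.96e-6	0.006	0
cg08368520	7	FOXK1	Body	OpenSea	52.9	7.8	44.5	8.0	-8.4	9.76e-4	0.038	0
cg01275887	7	FOXK1	Body	OpenSea	66.3	8.5	57.7	6.6	-8.5	7.38e-4	0.034	0
cg06443678	17		Intergenic	OpenSea	51.7	8.2	43.0	6.7	-8.7	2.98e-4	0.024	0
cg02514003	2		Intergenic	OpenSea	70.6	6.5	61.7	8.6	-8.9	2.53e-4	0.022	0
cg26504110	19	LTBP4	Body	Island	36.9	8.7	27.4	5.1	-9.5	2.98e-4	0.024	0
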