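probe_id	chromosome	gene	gene_regions	island_relation	before_mean	before_sd	after_mean	after_sd	difference	p_value	q_value	cross_reactive_bases
cg04090794	1	HSP90B3P	TSS1500	OpenSea	31.4	5.1	36.6	4.6	5.2	2.38e-7	0.004	0
cg05091570	1	NAV1	Body	Island	30.9	4.1	37.0	3.5	6.1	4.77e-7	0.004	0
cg01828733	1	NAV1	TSS200;Body	Island	40.6	4.1	46.2	4.3	5.5	1.19e-6	0.004	0
cg24553673	1	NR5A2	Body	S_Shore	33.1	4.7	39.9	3.8	6.8	2.38e-7	0.004	0
cg27183818	1		Intergenic	OpenSea	66.7	4.7	60.7	4.3	-6.0	7.15e-7	0.004	0
cg26091021	2		Intergenic	N_Shelf	38.9	3.6	45.4	3.3	6.5	2.38e-7	0.004	0
cg26297203	2		Intergenic	N_Shelf	52.5	3.2	57.6	3.0	5.0	1.19e-6	0.004	0
cg14091208	3	CCDC48	Body	Island	41.4	4.6	47.3	4.8	5.9	1.19e-6	0.004	0
cg09217023	3		Intergenic	OpenSea	57.2	4.0	62.6	3.2	5.5	2.38e-7	0.004	0
cg09380805	3		Intergenic	N_Shelf	29.0	4.0	35.7	3.8	6.6	7.15e-7	0.004	0
cg17103081	4	GPR125	Body	N_Shelf	63.4	5.2	68.4	4.9	5.1	1.19e-6	0.004	0
cg15133208	4	SNCA	5UTR	N_Shore	36.5	4.8	42.4	4.8	6.0	1.67e-6	0.004	0
cg14348967	4		Intergenic	OpenSea	31.9	5.2	37.5	4.4	5.6	1.67e-6	0.004	0
cg21817858	5		Intergenic	Island	46.2	5.2	51.8	4.4	5.6	2.38e-7	0.004	0
cg20934416	5		Intergenic	OpenSea	76.4	4.9	81.7	3.4	5.3	2.38e-6	0.005	0
cg14246190	6	EHMT2	Body	N_Shelf	65.1	4.3	70.4	3.4	5.3	2.38e-6	0.005	0
cg20284982	6	IER3	TSS1500	S_Shore	45.3	5.5	51.2	3.6	5.9	2.38e-6	0.005	48
cg12586150	6	SERPINB1	Body	N_Shore	51.9	5.2	58.4	4.7	6.5	2.38e-6	0.005	0
cg09871057	7	STX1A	Body	Island	52.3	3.5	57.4	3.2	5.1	1.19e-6	0.004	0
cg18550262	7		Intergenic	OpenSea	39.5	3.4	45.0	3.2	5.5	2.38e-7	0.004	0
cg00555695	8	PVT1	Body	OpenSea	40.3	3.9	45.8	3.4	5.5	2.38e-7	0.004	48
cg13832372	9	LHX6	Body	S_Shore	25.8	4.5	31.1	5.4	5.4	2.38e-6	0.005	0
cg02725718	10	ENKUR	Body	OpenSea	65.6	3.8	70.8	3.1	5.2	2.38e-6	0.005	47
cg12127706	11	CTTN	Body	OpenSea	54.3	3.9	59.5	3.7	5.2	1.19e-6	0.004	0
cg02093168	11	HCCA2	Body	OpenSea	61.2	5.8	67.5	4.2	6.4	1.19e-6	0.004	47
cg22041190	11	PKNOX2	5UTR	S_Shore	36.0	4.5	41.0	4.1	5.0	1.67e-6	0.004	0
cg12439006	11		Intergenic	OpenSea	64.5	4.2	69.7	3.2	5.2	2.38e-7	0.004	0
cg19896824	11		Intergenic	OpenSea	53.8	5.4	60.6	4.1	6.9	2.38e-7	0.004	0
cg21999471	11		Intergenic	OpenSea	41.1	5.3	46.7	3.6	5.6	2.38e-6	0.005	0
cg26828839	12	ANO2	Body	OpenSea	32.5	5.3	39.7	5.5	7.1	1.19e-6	0.004	0
cg13203394	12	ITPR2	Body	OpenSea	56.8	4.4	63.3	3.2	6.5	4.77e-7	0.004	0
cg26119796	13	RB1	Body	S_Shore	57.0	4.8	62.4	4.5	5.4	1.67e-6	0.004	47
cg00808648	14	PACS2	TSS1500	N_Shore	44.0	4.1	49.3	4.1	5.3	4.77e-7	0.004	0
cg22396498	15	CRTC3	Body	OpenSea	59.5	4.5	64.6	5.1	5.1	1.19e-6	0.004	0
cg07299078	16	KIFC3	Body;5UTR	OpenSea	49.6	4.3	55.9	4.9	6.4	2.38e-7	0.004	48
cg05797594	16	MIR1910;C16orf74	TSS1500;5UTR	OpenSea	51.5	5.1	57.2	2.9	5.6	2.38e-6	0.005	47
cg05516390	16	ZFHX3	5UTR	N_Shelf	41.8	4.4	49.8	4.4	8.0	1.19e-6	0.004	0
cg06078469	17	MSI2	Body	S_Shore	43.5	3.6	48.8	4.2	5.4	4.77e-7	0.004	0
cg22386583	17	RPTOR	Body	OpenSea	51.2	3.8	57.0	3.5	5.8	4.77e-7	0.004	0
cg11225357	17		Intergenic	OpenSea	45.1	4.1	50.6	3.9	5.5	1.19e-6	0.004	0
cg20811236	18		Intergenic	N_Shore	60.9	5.3	68.2	4.9	7.3	4.77e-7	0.004	0
cg21685776	18		Intergenic	S_Shore	51.4	4.4	56.6	4.8	5.2	7.15e-7	0.004	0
cg21520111	19	TRPM4	Body	Island	53.4	3.4	59.0	4.0	5.5	4.77e-7	0.004	0
cg21427956	20	C20orf160	3UTR	S_Shore	37.5	3.8	43.1	4.3	5.6	1.19e-6	0.004	0
cg08587504	20	LOC647979	TSS1500	S_Shore	62.7	3.4	68.0	3.0	5.3	2.38e-6	0.005	0
cg10854441	22	MLC1	TSS1500	N_Shelf	51.3	4.9	57.1	4.3	5.9	1.67e-6	0.004	0
cg04065832	X	CDX4	1stExon	Island	50.8	4.4	56.8	4.6	6.0	2.38e-6	0.005	0
cg19926635	X	KCND1	3UTR	S_Shelf	49.8	4.4	55.2	3.9	5.4	1.19e-6	0.004	0
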