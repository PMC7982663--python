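category	trait	rsid	gene	study_quality	interaction_type	variant_nature	plausibility	n_studies	total_subjects	mechanism_knowledge	curator_label
nutrition	Homocysteine levels	rs1801133	MTHFR	A	direct	causal	high	70	>100000	high	convincing
nutrition	Alzheimer's	rs429358,rs7412	APOE	A	direct	causal	high	146	>100000	high	convincing
nutrition	Alcohol dependence	rs1229984	ADH1B	A	direct	causal	high	59	>100000	high	convincing
nutrition	Greater total body adiposity	rs9939609	FTO	A	direct	causal	high	25	>100000	medium	convincing
nutrition	Vitamin D metabolism	rs4588	GC	B	direct	causal	high	21	>100000	high	convincing
nutrition	Vitamin B12 level	rs602662	FUT2	A	direct	causal	high	6	>9000	high	convincing
nutrition	Vitamin C level	rs33972313	SLC23A1	A	direct	causal	high	12	>100000	high	convincing
nutrition	Vitamin E level	rs964184	BUD13/ZNF259	B	direct	causal	high	4	>10000	high	convincing
nutrition	Iron overload / hemochromatosis	rs1800562	HFE	B	direct	causal	high	4	>5000	high	convincing
nutrition	Saturated fat / risk of T2D	rs1137101	LEPR	C	indirect	causal	high	12	>10000	medium	convincing
nutrition	Polyunsaturated fatty acids	rs174547	FADS1	C	direct	causal	high	11	3713	medium	convincing
nutrition	Lactose persistence	rs4988235	MCM6-LCT	A	direct	causal	high	>10	>100000	high	convincing
nutrition	Celiac disease	rs2187668	HLA-DQA1	A	direct	causal	high	many	7249	high	convincing
nutrition	Saturated fat	rs5082	APOA2	B	direct	causal	high	3	2856	medium	probable
nutrition	Vitamin A level	rs6564851	BCO1	C	direct	causal	high	4	328	medium	possible
nutrition	Total carbohydrates	rs7578326	IRS1	B	indirect	causal	high	2	~2000	medium	possible
nutrition	Total carbohydrates	rs2943641	IRS1	B	indirect	causal	high	2	~2000	medium	possible
nutrition	Sugar	rs7903146	TCF7L2	A	indirect	causal	high	2	26905	medium	possible
nutrition	Alcohol metabolism	rs698	ADH1C	C	direct	causal	high	many	>100000	high	possible
nutrition	Sweet foods / sweet tooth	rs838133	FGF21	A	direct	causal	medium	1	6514	high	not_demonstrated
nutrition	Vitamin B6 level	rs4654748	ALPL	B	direct	causal	high	1	~3000	high	not_demonstrated
nutrition	Total carbohydrates	rs2241201	MMAB	C	indirect	causal	high	1	920	low	not_demonstrated
nutrition	Fiber	rs4457053	ZBED3	B	indirect	causal	high	1	26905	medium	not_demonstrated
nutrition	Fiber	rs10923931	NOTCH2	B	indirect	causal	high	1	26905	medium	not_demonstrated
nutrition	Sugar	rs12255372	TCF7L2	B	indirect	causal	high	2	26979	medium	not_demonstrated
nutrition	Total fat	rs324420	FAAH	C	direct	causal	high	5	>5000	medium	not_demonstrated
nutrition	Saturated fat	rs12449157	GFOD2	D	direct	causal	high	1	41	medium	not_demonstrated
nutrition	Omega-3 fatty acids	rs17300539	ADIPOQ	C	direct	causal	high	1	310	medium	not_demonstrated
nutrition	Saturated fatty acids	rs1800629	TNF	C	indirect	causal	high	2	472	medium	not_demonstrated
nutrition	Protein	rs12785878	DHCR7	D	indirect	causal	high	1	732	medium	not_demonstrated
nutrition	Calcium	rs2228570	VDR	C	direct	causal	high	3	>5000	medium	not_demonstrated
nutrition	Zinc	rs73924411	SLC30A3	D	direct	causal	high	2	350	low	not_demonstrated
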