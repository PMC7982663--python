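category	trait	rsid	gene	study_quality	interaction_type	variant_nature	plausibility	n_studies	total_subjects	mechanism_knowledge	curator_label
fitness	VO2max trainability	21 SNPs	Multiple	A	direct	causal	high	35	>1000	medium	convincing
fitness	Muscle performance	rs1815739	ACTN3	A	indirect	causal	high	24	>1000	high	convincing
fitness	Increased exercise performance with caffeine	rs762551	CYP1A2	C	direct	causal	high	7	250	high	probable
fitness	Endurance	rs4253778	PPARA	B	indirect	causal	medium	6	3267	high	probable
fitness	Lactate blood levels	rs1049434	MCT1	B	direct	causal	high	4	2048	high	probable
fitness	Osmotic balance by water support	rs1049305	AQP1	B	indirect	causal	high	3	2613	medium	probable
fitness	Performance	rs12594956	NRF-2	C	indirect	causal	high	4	1598	medium	probable
fitness	Glucose transportation and lipid and glucose oxidation	rs8192678	PPARGC1A	C	indirect	causal	high	5	409	medium	possible
fitness	Endurance	rs12722	COL5A1	C	indirect	causal	high	3	952	medium	possible
fitness	Elite endurance	rs4994	ADRB3	D	indirect	causal	high	2	453	low	not_demonstrated
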