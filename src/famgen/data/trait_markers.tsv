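category	trait	rsid	gene	strand_alleles	effect_allele	model	interp_0	dir_0	interp_1	dir_1	interp_2	dir_2
fitness	Muscle performance	rs1815739	ACTN3	C/T	T	genotype-table	RR: two functional alpha-actinin-3 alleles; fast-twitch performance profile	favorable	XR: one functional alpha-actinin-3 allele; intermediate muscle performance profile	neutral	XX: alpha-actinin-3 deficient; associated with lower fast-twitch fiber percentage and potentially increased injury risk	unfavorable
fitness	Increased exercise performance with caffeine	rs762551	CYP1A2	A/C	A	genotype-table	CC: diminished exercise performance when combined with caffeine intake	unfavorable	AC: no effect of caffeine intake on exercise performance	neutral	AA: improved exercise performance when combined with caffeine intake	favorable
fitness	Endurance	rs4253778	PPARA	G/C	G	dominant	CC: no endurance-associated G allele present	neutral	G allele present: associated with higher endurance-sport ability	favorable	GG: associated with higher endurance-sport ability	favorable
fitness	Lactate blood levels	rs1049434	MCT1	T/A	T	genotype-table	AA: typical lactate transport	neutral	TA: one lower-lactate-associated allele	neutral	TT: associated with lower blood lactate levels	favorable
fitness	Osmotic balance by water support	rs1049305	AQP1	C/G	C	dominant	GG: no C allele; typical fluid-loss profile during exercise	neutral	C allele present: associated with faster cardiorespiratory endurance and fluid balance	favorable	CC: associated with faster cardiorespiratory endurance and fluid balance	favorable
fitness	Performance	rs12594956	NRF-2	A/C	A	recessive	CC: not associated with the endurance effect allele	neutral	CA: not associated with the endurance effect allele	neutral	AA: associated with endurance performance	favorable
nutrition	Homocysteine levels	rs1801133	MTHFR	G/A	A	genotype-table	GG: typical homocysteine levels and folic acid processing	neutral	GA: moderately higher homocysteine levels	neutral	AA: higher homocysteine levels and reduced folic acid processing	unfavorable
nutrition	Vitamin B12 level	rs602662	FUT2	G/A	A	dominant	GG: predicted lower circulating vitamin B12 levels	unfavorable	A allele present: predicted higher circulating vitamin B12 levels	favorable	AA: predicted higher circulating vitamin B12 levels	favorable
nutrition	Vitamin C level	rs33972313	SLC23A1	C/T	T	dominant	CC: typical circulating L-ascorbic acid transport	neutral	T allele present: associated with reduced circulating L-ascorbic acid concentrations	unfavorable	TT: associated with reduced circulating L-ascorbic acid concentrations	unfavorable
nutrition	Vitamin D metabolism	rs4588	GC	G/T	T	dominant	GG: typical vitamin D binding protein; expected response to vitamin D supplements	favorable	T allele present: altered vitamin D binding protein; predicted weaker response to vitamin D supplements	unfavorable	TT: altered vitamin D binding protein; predicted weaker response to vitamin D supplements	unfavorable
nutrition	Vitamin E level	rs964184	BUD13/ZNF259	C/G	G	genotype-table	CC: typical plasma alpha-tocopherol concentration	neutral	GC: one allele associated with higher plasma alpha-tocopherol	favorable	GG: associated with higher plasma alpha-tocopherol concentration	favorable
nutrition	Greater total body adiposity	rs9939609	FTO	T/A	A	genotype-table	TT: no adiposity risk allele	favorable	TA: one risk allele; BMI increase of ~0.4 kg/m2 per A allele	unfavorable	AA: two risk alleles; predicted increase in total body adiposity	unfavorable
nutrition	Saturated fat	rs5082	APOA2	G/A	G	recessive	AA: no associated effect of saturated-fat intake	neutral	GA: no associated effect of saturated-fat intake	neutral	GG: associated with higher obesity risk under high saturated-fat intake	unfavorable
nutrition	Polyunsaturated fatty acids	rs174547	FADS1	T/C	C	dominant	TT: no associated effect on polyunsaturated fatty acid metabolism	neutral	C allele present: altered fatty-acid desaturase activity and PUFA metabolism	unfavorable	CC: altered fatty-acid desaturase activity and PUFA metabolism	unfavorable
nutrition	Saturated fat / risk of T2D	rs1137101	LEPR	A/G	G	dominant	AA: no risk allele; typical response to total fat intake	neutral	G allele present: higher risk of obesity and high cholesterol under high total fat intake	unfavorable	GG: higher risk of obesity and high cholesterol under high total fat intake	unfavorable
nutrition	Iron overload / hemochromatosis	rs1800562	HFE	G/A	A	genotype-table	GG: no hemochromatosis-associated allele	favorable	GA: carrier of the allele causing most hereditary hemochromatosis	neutral	AA: strongly associated with hereditary hemochromatosis (iron overload)	unfavorable
nutrition	Celiac disease	rs2187668	HLA-DQA1	C/T	T	dominant	CC: not associated with celiac disease risk	favorable	T allele present: increased celiac disease risk	unfavorable	TT: increased celiac disease risk	unfavorable
nutrition	Lactose persistence	rs4988235	MCM6-LCT	G/A	A	dominant	GG: lactase non-persistent; increased likelihood of lactose maldigestion	unfavorable	Lactase-persistence allele present in heterozygous state: dominant effect, lactose digester	favorable	AA: lactase persistent; lactose digester	favorable
nutrition	Alcohol dependence	rs1229984	ADH1B	C/T	T	dominant	CC: typical alcohol dehydrogenase activity	neutral	T allele present: faster ethanol oxidation, associated with lower likelihood of alcohol dependence	favorable	TT: faster ethanol oxidation, associated with lower likelihood of alcohol dependence	favorable
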