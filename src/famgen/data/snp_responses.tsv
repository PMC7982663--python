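rsid	gene	drug	genotype	category	annotation
rs12979860	IL28B	PEG-IFN-alpha + ribavirin	CC	favorable	Viral eradication in ~80% of CC hepatitis C patients under PEG-IFN-alpha plus ribavirin
rs12979860	IL28B	PEG-IFN-alpha + ribavirin	CT	intermediate	Intermediate treatment response for CT genotype
rs12979860	IL28B	PEG-IFN-alpha + ribavirin	TT	unfavorable	Viral eradication in only ~25% of TT hepatitis C patients
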