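gene	allele	activity	function	defining_variants
CYP2C9	*1	1	normal
CYP2C9	*2	0.5	decreased	10:96702047:C:T
CYP2C9	*3	0	none	10:96741053:A:C
CYP2C19	*1	1	normal
CYP2C19	*2	0	none	10:96541616:G:A
CYP2C19	*4	0	none	10:96602623:A:G
CYP2C19	*17	1	increased	10:96521657:C:T
CYP2C19	*4A	0	none	10:96521657:C:T;10:96602623:A:G
CYP2D6	*1	1	normal
CYP2D6	*2	1	normal	22:42523943:A:G;22:42522613:G:C
CYP2D6	*4	0	none	22:42526694:C:T;22:42524947:C:T;22:42522613:G:C
CYP2D6	*10	0.25	decreased	22:42526694:C:T;22:42522613:G:C
CYP2D6	*41	0.5	decreased	22:42523943:A:G;22:42523805:C:T;22:42522613:G:C
CYP2D6	*17	1	normal	22:42525772:G:A;22:42522613:G:C
CYP2D6	*20	0	none	22:42525244:G:GG
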