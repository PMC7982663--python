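drug	diplotype	cogenotype	fraction	source
warfarin	*1/*1	CC	1.00	FDA-label-derived
warfarin	*1/*1	CT	0.80	interpolated
warfarin	*1/*1	TT	0.60	interpolated
warfarin	*1/*2	CC	0.80	interpolated
warfarin	*1/*2	CT	0.60	FDA-label-derived
warfarin	*1/*2	TT	0.60	FDA-label-derived
warfarin	*1/*3	CC	0.70	interpolated
warfarin	*1/*3	CT	0.50	interpolated
warfarin	*1/*3	TT	0.40	interpolated
warfarin	*2/*2	CC	0.60	interpolated
warfarin	*2/*2	CT	0.40	interpolated
warfarin	*2/*2	TT	0.20	FDA-label-derived
warfarin	*2/*3	CC	0.40	interpolated
warfarin	*2/*3	CT	0.30	interpolated
warfarin	*2/*3	TT	0.20	interpolated
warfarin	*3/*3	CC	0.30	interpolated
warfarin	*3/*3	CT	0.20	interpolated
warfarin	*3/*3	TT	0.10	interpolated
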