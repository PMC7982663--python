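rsid	chrom	pos	ref	alt	favorable_allele
rs9000001	1	10000100	A	G	G
rs9000002	1	20000100	C	T	C
rs9000003	2	10000200	G	A	A
rs9000004	2	20000200	T	C	C
rs9000005	3	10000300	A	C	A
rs9000006	3	20000300	G	T	T
rs9000007	4	10000400	C	A	C
rs9000008	5	10000500	T	G	G
rs9000009	6	10000600	A	G	A
rs9000010	7	10000700	C	T	T
rs9000011	8	10000800	G	A	G
rs9000012	9	10000900	T	C	T
rs9000013	10	10001000	A	C	C
rs9000014	11	10001100	G	T	G
rs9000015	12	10001200	C	A	A
rs9000016	13	10001300	T	G	T
rs9000017	14	10001400	A	G	G
rs9000018	15	10001500	C	T	C
rs9000019	16	10001600	G	A	A
rs9000020	17	10001700	T	C	T
rs9000021	18	10001800	A	C	A
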