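feature_id	closest_left	closest_right	mean_a	mean_b	fdr
lincRNA.27817	SLC25A53	FAM199X	0	5.13	0.008
lincRNA.26835	SHROOM2	CLCN4	12.82	0	0.008
lincRNA.25403	SMYD2	COL12A1	14.92	2.02	0.014
lincRNA.12819	ENSOARG00000015627	LGSN	47.27	0.47	0.035
lincRNA.16164	ENSOARG00000004542	TSHZ1	3.14	0	0.059
lincRNA.21492	CCM2	MYO1G	64.52	19.27	0.059
lincRNA.3473	ACACA	C17orf78	80.07	303.52	0.066
ilncRNA.20260	PRDM4	PRDM4	277.18	26.50	0.082
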