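lnc_id	category	chrom	start	end	qtl_id	qtl_chrom	qtl_start	qtl_end	trait	closest_left	closest_right
lincRNA.26756	lincRNA	9	93793209	93797530	127008	9	93460494	93799321	Tail fat deposition	DSCC1
lincRNA.17595	lincRNA	25	7612489	7615461	127015	25	202582	7694641	Tail fat deposition		TOMM20
lincRNA.6399	lincRNA	13	63356541	63371778	127012	13	62767123	63461553	Tail fat deposition		ITCH
lincRNA.2930	lincRNA	10	28841431	28846038	126989	10	26820350	32294189	Tail fat deposition		N4BP2L1
lincRNA.2940	lincRNA	10	30330057	30332096	126989	10	26820350	32294189	Tail fat deposition	MEDAG	ALOX5AP
lincRNA.18895	lincRNA	3	38182529	38199498	126987	3	37167143	43070322	Tail fat deposition	PCBP1	ASPRV1
ilncRNA.2931	ilncRNA	10	28848713	28850535	126989	10	26820350	32294189	Tail fat deposition	N4BP2L1	N4BP2L1
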