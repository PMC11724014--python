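sample_id	gene	category	biallelic
PUB-WAF8U	PALB2	WT_LOST	True
PUB-RRQTJ	PALB2	WT_LOST	True
PUB-XXXXX	PALB2	WT_LOST	True
PUB-EVZW5	MRE11A	HETEROZYGOUS	False
PUB-ROW8I	MRE11A	HETEROZYGOUS	False
PUB-2LRZJ	ATM	WT_LOST	True
PUB-H03DK	ATM	WT_LOST	True
PUB-P2A20	ATM	WT_LOST_BY_SOMATIC_HIT	True
PUB-GHWX3	ATM	HETEROZYGOUS	False
PUB-BAD3Y	ATM	HETEROZYGOUS	False
PUB-1B2SB	ERCC3	VARIANT_LOST	False
PUB-7BG9V	ERCC3	VARIANT_LOST	False
PUB-KBIYV	ERCC3	HETEROZYGOUS	False
PUB-IBLSG	BLM	WT_LOST	True
PUB-1G5DH	BLM	HET_WITH_SOMATIC_HIT_PHASE_UNKNOWN	True
PUB-0RH0G	BLM	VARIANT_LOST	False
PUB-RTN4O	FANCM	WT_LOST	True
PUB-Q6QAX	FANCM	HETEROZYGOUS	False
PUB-R0JXJ	MAP6D1	HET_ONE_ALLELE_METHYLATED	False
PUB-HLQJ5	MAP6D1	VARIANT_LOST_WT_METHYLATED	True
PUB-PRTO5	MAP6D1	HET_ONE_ALLELE_METHYLATED	False
PUB-MWTHR	RPA3	HETEROZYGOUS	False
PUB-UGMNM	RPA3	HETEROZYGOUS	False
PUB-XCS9D	STARD6	HETEROZYGOUS	False
PUB-BGL6F	STARD6	WT_LOST	True
PUB-C7OZT	LLGL2	VARIANT_LOST_WT_METHYLATED	True
PUB-EJ4NC	LLGL2	WT_LOST	True
PUB-LKOD9	LLGL2	WT_LOST	True
PUB-U7P7F	CCDC88B	HETEROZYGOUS	False
PUB-WF2F5	CCDC88B	HETEROZYGOUS	False
PUB-J3ODA	CCDC88B	HETEROZYGOUS	False
PUB-58A4L	FBLIM1	HETEROZYGOUS	False
PUB-IXQKT	FBLIM1	HETEROZYGOUS	False
PUB-9XXOO	IFIT2	WT_LOST	True
PUB-AF099	IFIT2	HETEROZYGOUS	False
PUB-SV5CQ	IFIT2	HETEROZYGOUS	False
PUB-SUGLY	MIPOL1	HET_ONE_ALLELE_METHYLATED	False
PUB-NFUNH	MIPOL1	HET_WT_METHYLATED	True
PUB-HLQJ5	MIPOL1	HET_WT_METHYLATED	True
PUB-IFNQ0	TTC24	HETEROZYGOUS	False
PUB-QY8W8	TTC24	HETEROZYGOUS	False
PUB-SWU2E	SLC38A8	HETEROZYGOUS	False
PUB-CX65G	SLC38A8	WT_LOST	True
PUB-BFSYR	ANKAR	HETEROZYGOUS	False
PUB-8U010	ANKAR	HETEROZYGOUS	False
PUB-5IGWB	ANKAR	HETEROZYGOUS	False
PUB-88NOV	ANKAR	HETEROZYGOUS	False
PUB-WANJC	ANKAR	HETEROZYGOUS	False
PUB-EVZW5	SCYL3	HET_WT_METHYLATED	True
PUB-9SR2V	SCYL3	WT_LOST	True
PUB-9ZUZK	SCYL3	HETEROZYGOUS	False
PUB-M4AJ2	MMAA	HETEROZYGOUS	False
PUB-2TCR0	MMAA	HETEROZYGOUS	False
PUB-ATZ8R	ZNF418	HET_ONE_ALLELE_METHYLATED	False
PUB-YS9UF	ZNF418	HET_ONE_ALLELE_METHYLATED	False
PUB-K56S6	LRRC56	HETEROZYGOUS	False
PUB-IBW33	HARS2	WT_LOST	True
PUB-FXXFL	HARS2	HET_ONE_ALLELE_METHYLATED	False
PUB-ZPSA2	PRKACG	HETEROZYGOUS	False
PUB-SKYSL	PRKACG	HETEROZYGOUS	False
PUB-9ZUZK	VSIG1	WT_LOST	True
PUB-A6JHW	ZNF616	HETEROZYGOUS	False
PUB-JOPWC	ZNF616	HETEROZYGOUS	False
PUB-0GFYL	ZNF616	HETEROZYGOUS	False
PUB-CX65G	TBXAS1	HETEROZYGOUS	False
PUB-7IV8M	CDH23	HET_ONE_ALLELE_METHYLATED	False
PUB-COP45	CDH23	HET_WT_METHYLATED	True
PUB-EOVJJ	LTBP1	HET_WT_METHYLATED	True
PUB-S3571	ADGRD1	HETEROZYGOUS	False
PUB-YU7VB	DLGAP5	HETEROZYGOUS	False
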