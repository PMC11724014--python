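gene	group	x_linked	case_alleles	case_total	gnomad_alleles	gnomad_total	mgrb_alleles	mgrb_total	lifepool_alleles	lifepool_total	n_tumours
PALB2	proposed	False	3	992	86	118190	4	5144	3	3406	3
ATM	proposed	False	4	992	195	118190	13	5144	3	3406	5
MRE11A	proposed	False	2	992	57	118190	1	5144	2	3406	2
ERCC3	proposed	False	3	992	125	118190	2	5144	2	3406	3
BLM	proposed	False	3	992	131	118190	5	5144	3	3406	3
FANCM	proposed	False	2	992	344	118190	11	5144	7	3406	2
MAP6D1	candidate	False	3	992	9	118190	3	5144	1	3406	3
SLC12A4	candidate	False	5	992	54	118190	6	5144	0	3406	5
SORD	candidate	False	6	992	89	118190	26	5144	0	3406	4
CPT1B	candidate	False	4	992	36	118190	2	5144	0	3406	2
ZBTB45	candidate	False	4	992	37	118190	3	5144	0	3406	4
LOXL2	candidate	False	4	992	39	118190	3	5144	2	3406	3
SSX3	candidate	True	3	992	11	118190	1	5144	0	3406	2
ZCCHC4	candidate	False	12	992	444	118190	20	5144	8	3406	10
RPA3	candidate	False	3	992	18	118190	2	5144	1	3406	2
IMPDH2	candidate	False	3	992	19	118190	1	5144	0	3406	3
GPALPP1	candidate	False	3	992	19	118190	2	5144	0	3406	3
WRAP53	candidate	False	4	992	49	118190	2	5144	1	3406	4
STARD6	candidate	False	3	992	22	118190	0	5144	2	3406	2
LLGL2	candidate	False	4	992	55	118190	0	5144	3	3406	3
CCDC88B	candidate	False	4	992	57	118190	2	5144	4	3406	3
FBLIM1	candidate	False	3	992	26	118190	2	5144	0	3406	2
IFIT2	candidate	False	4	992	58	118190	3	5144	1	3406	3
MIPOL1	candidate	False	4	992	60	118190	6	5144	3	3406	3
CCDC14	candidate	False	6	992	150	118190	9	5144	1	3406	6
TTC24	candidate	False	3	992	32	118190	0	5144	1	3406	2
SLC38A8	candidate	False	3	992	34	118190	2	5144	2	3406	2
ANKAR	candidate	False	6	992	174	118190	8	5144	11	3406	5
CARMIL2	candidate	False	3	992	36	118190	3	5144	1	3406	2
SCYL3	candidate	False	3	992	37	118190	6	5144	1	3406	3
MMAA	candidate	False	4	992	78	118190	4	5144	3	3406	2
ZNF418	candidate	False	5	992	127	118190	3	5144	3	3406	2
RAD1	candidate	False	5	992	129	118190	6	5144	2	3406	3
USP50	candidate	False	4	992	80	118190	2	5144	3	3406	4
RASSF7	candidate	False	3	992	41	118190	3	5144	1	3406	2
LRRC56	candidate	False	3	992	44	118190	1	5144	7	3406	1
HARS2	candidate	False	3	992	45	118190	2	5144	0	3406	2
PRKACG	candidate	False	3	992	46	118190	0	5144	6	3406	2
CDKL3	candidate	False	4	992	90	118190	7	5144	0	3406	2
ZNF616	candidate	False	4	992	91	118190	4	5144	2	3406	3
VSIG1	candidate	True	3	992	33	118190	2	5144	0	3406	1
ANKRD18A	candidate	False	3	992	47	118190	0	5144	3	3406	3
FAM216A	candidate	False	3	992	60	118190	7	5144	3	3406	2
TBXAS1	candidate	False	3	992	61	118190	3	5144	1	3406	1
CDH23	candidate	False	2	992	26	118190	4	5144	1	3406	2
LTBP1	candidate	False	2	992	28	118190	3	5144	0	3406	1
ADGRD1	candidate	False	2	992	46	118190	0	5144	2	3406	1
PLEKHA4	candidate	False	2	992	82	118190	4	5144	3	3406	2
DLGAP5	candidate	False	1	992	33	118190	1	5144	0	3406	1
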