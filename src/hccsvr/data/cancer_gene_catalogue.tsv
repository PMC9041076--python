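gene	role	source
CTNNB1	ONCOGENE	curated
PREX2	ONCOGENE	curated
NFE2L2	ONCOGENE	curated
SKP2	ONCOGENE	curated
ROBO1	ONCOGENE	curated
COL22A1	ONCOGENE	curated
SRGAP3	ONCOGENE	curated
PIK3CA	ONCOGENE	curated
KRAS	ONCOGENE	curated
NRAS	ONCOGENE	curated
HRAS	ONCOGENE	curated
BRAF	ONCOGENE	curated
MYC	ONCOGENE	curated
MYCN	ONCOGENE	curated
EGFR	ONCOGENE	curated
ERBB2	ONCOGENE	curated
MET	ONCOGENE	curated
ALK	ONCOGENE	curated
ROS1	ONCOGENE	curated
RET	ONCOGENE	curated
KIT	ONCOGENE	curated
PDGFRA	ONCOGENE	curated
FGFR1	ONCOGENE	curated
FGFR2	ONCOGENE	curated
FGFR3	ONCOGENE	curated
IDH1	ONCOGENE	curated
IDH2	ONCOGENE	curated
JAK2	ONCOGENE	curated
ABL1	ONCOGENE	curated
AKT1	ONCOGENE	curated
MTOR	ONCOGENE	curated
MDM2	ONCOGENE	curated
MDM4	ONCOGENE	curated
CCND1	ONCOGENE	curated
CCNE1	ONCOGENE	curated
CDK4	ONCOGENE	curated
CDK6	ONCOGENE	curated
GNAS	ONCOGENE	curated
GNAQ	ONCOGENE	curated
GNA11	ONCOGENE	curated
MAP2K1	ONCOGENE	curated
NOTCH1	ONCOGENE	curated
TERT	ONCOGENE	curated
AR	ONCOGENE	curated
ESR1	ONCOGENE	curated
FLT3	ONCOGENE	curated
NPM1	ONCOGENE	curated
EZH2	ONCOGENE	curated
RICTOR	ONCOGENE	curated
TP53	TSG	curated
ARID2	TSG	curated
KEAP1	TSG	curated
ARID1A	TSG	curated
ARID1B	TSG	curated
AXIN1	TSG	curated
RB1	TSG	curated
PTEN	TSG	curated
CDKN2A	TSG	curated
APC	TSG	curated
SMAD4	TSG	curated
ATM	TSG	curated
ATR	TSG	curated
BRCA1	TSG	curated
BRCA2	TSG	curated
NF1	TSG	curated
NF2	TSG	curated
VHL	TSG	curated
MLH1	TSG	curated
MSH2	TSG	curated
MSH6	TSG	curated
PMS2	TSG	curated
STK11	TSG	curated
TSC1	TSG	curated
TSC2	TSG	curated
FBXW7	TSG	curated
CREBBP	TSG	curated
EP300	TSG	curated
KMT2C	TSG	curated
KMT2D	TSG	curated
SETD2	TSG	curated
PBRM1	TSG	curated
BAP1	TSG	curated
SMARCA4	TSG	curated
SMARCB1	TSG	curated
CDH1	TSG	curated
CTCF	TSG	curated
WT1	TSG	curated
RUNX1	TSG	curated
DNMT3A	TSG	curated
TET2	TSG	curated
ASXL1	TSG	curated
SF3B1	TSG	curated
BCOR	TSG	curated
PTCH1	TSG	curated
ALB	OTHER_CANCER_GENE	curated
APOB	OTHER_CANCER_GENE	curated
CPS1	OTHER_CANCER_GENE	curated
HNF1A	OTHER_CANCER_GENE	curated
IL6ST	OTHER_CANCER_GENE	curated
TP63	OTHER_CANCER_GENE	curated
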