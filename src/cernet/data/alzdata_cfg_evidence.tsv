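Gene	eQTL	GWAS	PPI	Early_DEG	Pathology cor (abeta)	Pathology cor (tau)	CFG
C3	2	0	APP, PSEN1, PSEN2, MAPT	Yes	0.850, ***	0.761, ***	4
NCAPD2	41	0	MAPT	Yes	−0.090, ns	-0.801, ***	4
ADORA2B	7	0	–	Yes	0.725, ***	0.652, **	3
ATP1A2	1	0	–	Yes	0.460, **	-0.110, ns	3
CD9	2	0	–	Yes	0.873, ***	0.566, *	3
CTSB	NA	0	APP, APOE	Yes	0.801, ***	0.599, *	3
DAAM2	3	0	–	Yes	0.477, **	0.307, ns	3
EGR2	2	0	–	Yes	−0.376, *	−0.196, ns	3
GPR116	0	2	APP, PSEN1, PSEN2, MAPT, APOE	Yes	−0.045, ns	−0.023, ns	3
GPR34	1	NA	NA	Yes	0.852, ***	0.876, ***	3
GUCY1A3	3	0	–	yes	−0.191, ns	−0.729, **	3
GUCY1B3	1	0	–	yes	−0.246, ns	−0.581, *	3
NTRK2	1	0	APP, PSEN1, PSEN2	NA	0.543, ***	0.538, *	3
CCDC3	0	3	–	no	0.557, ***	0.824, ***	2
CCNF	1	0	PSEN1	NA	0.078, ns	−0.247, ns	2
CX3CR1	4	0	–	NA	0.832, ***	0.485, ns	2
EGR3	1	0	–	yes	−0.045, ns	0.474, ns	2
EZH2	4	0	PSEN2	NA	NA	NA	2
FERMT2	2	100	–	NA	NA	NA	2
FGFBP3	1	0	NA	NA	−0.642, ***	−0.251, ns	2
KIAA0101	1	5	–	NA	NA	NA	2
NEK2	2	0	MAPT	NA	NA	NA	2
OLIG1	3	0	–	yes	0.175, ns	−0.156, ns	2
TGFBI	0	0	APP, APOE	no	0.532, ***	0.426, ns	2
TPM2	1	0	APP	NA	0.049, ns	−0.420, ns	2
APLNR	NA	0	APP, PSEN1, APOE	NA	NA	NA	1
BIRC5	0	0	PSEN2, APOE	NA	−0.089, ns	0.058, ns	1
CDCA3	2	0	NA	NA	0.031, ns	0.025, ns	1
CENPH	0	0	PSEN2	NA	NA	NA	1
CKS1B	2	0	–	NA	NA	NA	1
F3	3	0	–	NA	NA	NA	1
KCNJ8	0	0	–	yes	0.028, ns	0.177, ns	1
KIF2C	0	0	PSEN1, PSEN2	NA	NA	NA	1
RASGRP2	2	0	–	NA	−0.262, ns	−0.200, ns	1
RNASEH2A	1	0	–	NA	NA	NA	1
RRM2	4	0	–	NA	−0.080, ns	−0.398, ns	1
SOX11	1	0	–	NA	NA	NA	1
SPC24	NA	0	PSEN2	NA	−0.030, ns	0.113, ns	1
STOM	1	0	–	NA	NA	NA	1
TESC	2	0	–	NA	−0.165, ns	0.376, ns	1
TOP2A	NA	0	–	Yes	0.065, ns	−0.229, ns	1
AFAP1L2	0	0	–	NA	NA	NA	0
LHFPL3	0	0	NA	NA	NA	NA	0
MKI67	0	0	–	NA	NA	NA	0
RASL12	0	0	–	NA	0.177, ns	0.291, ns	0
RGCC	NA	0	–	NA	NA	NA	0
SYNM	0	0	–	NA	NA	NA	0
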