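Probe	Chr	Symbol	Adjusted_p	Log2FC
hsa-circRNA2166-1	13	GPC5	2.24E-02	3.884989
hsa-circRNA2166-8	13	GPC5	3.01E-02	3.680999
hsa_circ_0100987	13	GPC5	1.73E-02	3.475474
hsa-circRNA2166-3	13	GPC5	2.37E-02	3.379621
hsa-circRNA2166-7	13	GPC5	3.44E-02	3.261531
hsa_circ_0100989	13	GPC5	1.90E-02	3.228973
hsa-circRNA2166-5	13	GPC5	2.65E-02	3.199123
hsa_circ_0100988	13	GPC5	3.94E-02	3.116365
hsa_circ_0136188	8	NEFL	2.49E-02	3.801573
hsa_circ_0136190	8	NEFL	1.25E-02	3.457988
hsa_circ_0136191	8	NEFL	1.60E-02	3.293959
hsa_circ_0136187	8	NEFL	1.79E-02	3.091531
hsa_circ_0043887	17	CNTNAP1	1.28E-02	3.575675
hsa_circ_0058363	2	TUBA4A	4.42E-02	3.430687
hsa_circ_0080947	7	SEMA3D	2.92E-02	3.252779
hsa-circRNA3152-8	16	CPNE7	1.21E-02	3.232047
hsa_circ_0131237	6	LPA	8.13E-03	3.149747
hsa_circ_0042551	17	ALDOC	3.52E-02	3.112533
hsa_circ_0131986	6	BEND6	1.80E-02	3.087802
hsa_circ_0095633	11	LUZP2	1.12E-02	3.069187
hsa_circ_0073309	5	GPR98	2.59E-02	−3.75617
hsa_circ_0073310	5	GPR98	3.18E-02	−3.62152
hsa_circ_0073325	5	GPR98	1.88E-02	−3.51677
hsa_circ_0073306	5	GPR98	3.39E-02	−3.48852
hsa_circ_0073290	5	GPR98	3.54E-02	−3.47832
hsa_circ_0073289	5	GPR98	2.68E-02	−3.46597
hsa_circ_0073304	5	GPR98	2.97E-02	−3.42304
hsa_circ_0129959	5	GPR98	2.78E-02	−3.36695
hsa_circ_0129954	5	GPR98	2.56E-02	−3.36345
hsa_circ_0073326	5	GPR98	2.45E-02	−3.36036
hsa_circ_0129974	5	GPR98	2.40E-02	−3.34809
hsa_circ_0073284	5	GPR98	3.77E-02	−3.32294
hsa_circ_0073291	5	GPR98	3.23E-02	−3.31658
hsa_circ_0135183	7	DLX6-AS1	4.97E-02	−3.72999
hsa_circ_0043539	17	TOP2A	1.36E-02	−3.52281
hsa-circRNA11458-30	17	TOP2A	1.40E-02	−3.46963
hsa_circ_0015764	1	ASPM	1.29E-02	−3.39534
hsa_circ_0015766	1	ASPM	1.63E-02	−3.35924
hsa_circ_0135184	7	DLX6-AS1	4.03E-02	−3.37768
hsa-circRNA11595-11	17	BRIP1	2.46E-02	−3.33256
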