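owner	key	weight
TIG	CCL5	0.008346
TIG	CD27	0.072293
TIG	CD274	0.042853
TIG	CD276	-0.0239
TIG	CD8A	0.031021
TIG	CMKLR1	0.151253
TIG	CXCL9	0.074135
TIG	CXCR6	0.004313
TIG	HLA-DQA1	0.020091
TIG	HLA-DRB1	0.058806
TIG	HLA-E	0.07175
TIG	IDO1	0.060679
TIG	LAG3	0.123895
TIG	NKG7	0.075524
TIG	PDCD1LG2	0.003734
TIG	PSMB10	0.032999
TIG	STAT1	0.250229
TIG	TIGIT	0.084767
Immunophenoscore	HLA-A	1.0
Immunophenoscore	HLA-B	1.0
Immunophenoscore	HLA-C	1.0
Immunophenoscore	HLA-DPA1	1.0
Immunophenoscore	HLA-DPB1	1.0
Immunophenoscore	HLA-E	1.0
Immunophenoscore	HLA-F	1.0
Immunophenoscore	B2M	1.0
Immunophenoscore	TAP1	1.0
Immunophenoscore	TAP2	1.0
Immunophenoscore	CD27	1.0
Immunophenoscore	CD28	1.0
Immunophenoscore	CD40LG	1.0
Immunophenoscore	ICOS	1.0
Immunophenoscore	TNFRSF4	1.0
Immunophenoscore	TNFRSF9	1.0
Immunophenoscore	TNFRSF14	1.0
Immunophenoscore	TNFRSF18	1.0
Immunophenoscore	PDCD1	-1.0
Immunophenoscore	CTLA4	-1.0
Immunophenoscore	LAG3	-1.0
Immunophenoscore	TIGIT	-1.0
Immunophenoscore	HAVCR2	-1.0
Immunophenoscore	CD274	-1.0
Immunophenoscore	PDCD1LG2	-1.0
Immunophenoscore	IDO1	-1.0
Immunophenoscore	VSIR	-1.0
Immunophenoscore	BTLA	-1.0
Immunophenoscore	CD8A	1.0
Immunophenoscore	GZMB	1.0
Immunophenoscore	PRF1	1.0
Immunophenoscore	IFNG	1.0
Immunophenoscore	GZMA	1.0
Immunophenoscore	NKG7	1.0
Immunophenoscore	KLRD1	1.0
Immunophenoscore	EOMES	1.0
Immunophenoscore	FOXP3	-1.0
Immunophenoscore	IL2RA	-1.0
Immunophenoscore	CCR8	-1.0
Immunophenoscore	IKZF2	-1.0
Immunophenoscore	TGFB1	-1.0
Immunophenoscore	ARG1	-1.0
Immunophenoscore	NOS2	-1.0
Immunophenoscore	CD33	-1.0
IRG	IL1B	0.32
IRG	CXCL8	0.27
IRG	LTA	-0.21
IRG	CD70	0.18
IRG	TNFRSF13C	-0.15
IRG	IL13RA2	0.41
IRG	TFRC	0.22
IRG	SDC1	0.19
IRG	PLAU	0.35
IRG	OSM	-0.12
IRG	IL17RD	0.24
MPS	MLANA	0.445
MPS	PMEL	-0.868
MPS	TYR	-0.467
MPS	TYRP1	-0.941
MPS	DCT	-0.129
MPS	MITF	-0.311
MPS	SOX10	-0.143
MPS	EDNRB	0.959
MPS	KIT	-0.926
MPS	PAX3	0.369
MPS	RAB27A	0.486
MPS	GPR143	-0.87
MPS	OCA2	-0.86
MPS	SLC45A2	-0.956
MPS	TRPM1	-0.973
MPS	CDH1	-0.751
MPS	CDH2	-0.381
MPS	ZEB1	0.478
MPS	ZEB2	0.51
MPS	TWIST1	0.978
MPS	SNAI1	0.897
MPS	SNAI2	0.851
MPS	VIM	0.623
MPS	NGFR	-0.462
MPS	AXL	-0.567
MPS	ERBB3	0.731
MPS	SOX2	0.777
MPS	NES	0.421
MPS	POU3F2	-0.622
MPS	TFAP2A	0.759
MPS	TFAP2B	0.723
MPS	GAS7	0.394
MPS	SEMA3B	0.678
MPS	PLXNC1	0.723
MPS	MBP	0.562
MPS	PLP1	0.665
MPS	S100B	-0.857
MPS	GFAP	0.716
MPS	L1CAM	0.878
MPS	NRG1	-0.222
MPS	FGF13	-0.235
MPS	DLL3	0.119
MPS	ASCL1	-0.948
MPS	SOX4	0.584
MPS	BCHE	0.728
IMS	IMS_GS01	-0.3
IMS	IMS_GS02	0.179
IMS	IMS_GS03	-0.803
IMS	IMS_GS04	-0.722
IMS	IMS_GS05	0.405
IMS	IMS_GS06	-0.675
IMS	IMS_GS07	-0.958
IMS	IMS_GS08	0.493
IMS	IMS_GS09	-0.656
IMS	IMS_GS10	-0.473
IMS	IMS_GS11	0.604
IMS	IMS_GS12	-0.632
IMS	IMS_GS13	0.561
IMS	IMS_GS14	0.546
IMS	IMS_GS15	0.778
IMS	IMS_GS16	-0.661
IMS	IMS_GS17	0.105
IMS	IMS_GS18	0.615
IMS	IMS_GS19	0.628
IMS	IMS_GS20	0.411
IMS	IMS_GS21	-0.872
IMS	IMS_GS22	-0.814
IMS	IMS_GS23	-0.457
IMS	IMS_GS24	-0.378
IMS	IMS_GS25	-0.577
IMS	IMS_GS26	-0.687
IMS	IMS_GS27	-0.626
PASS-PRE	PASS_GS01	0.473
PASS-PRE	PASS_GS02	0.786
PASS-PRE	PASS_GS03	0.118
PASS-PRE	PASS_GS04	0.725
PASS-PRE	PASS_GS05	0.902
PASS-PRE	PASS_GS06	0.522
PASS-PRE	PASS_GS07	-0.771
PASS-PRE	PASS_GS08	0.344
PASS-PRE	PASS_GS09	0.92
PASS-PRE	PASS_GS10	0.379
PASS-PRE	PASS_GS11	0.837
PASS-PRE	PASS_GS12	-0.216
PASS-PRE	PASS_GS13	-0.214
PASS-PRE	PASS_GS14	0.686
PASS-PRE	PASS_GS15	0.622
PASS-ON	PASS_GS01	0.963
PASS-ON	PASS_GS02	-0.352
PASS-ON	PASS_GS03	-0.976
PASS-ON	PASS_GS04	0.783
PASS-ON	PASS_GS05	0.946
PASS-ON	PASS_GS06	0.589
PASS-ON	PASS_GS07	-0.195
PASS-ON	PASS_GS08	0.655
PASS-ON	PASS_GS09	-0.745
PASS-ON	PASS_GS10	0.953
PASS-ON	PASS_GS11	-0.183
PASS-ON	PASS_GS12	-0.568
PASS-ON	PASS_GS13	0.484
PASS-ON	PASS_GS14	-0.925
PASS-ON	PASS_GS15	0.951
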