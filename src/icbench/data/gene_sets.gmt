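PD-L1	transcribed from source publication	CD274
PD-1	transcribed from source publication	PDCD1
PD-L2	transcribed from source publication	PDCD1LG2
CX3CL1	transcribed from source publication	CX3CL1
CTLA-4	transcribed from source publication	CTLA4
HLA-DRA	transcribed from source publication	HLA-DRA
CXCL9	transcribed from source publication	CXCL9
HRH1	transcribed from source publication	HRH1
CYT	transcribed from source publication	GZMA	PRF1
IFN-gamma	transcribed from source publication	IFNG	STAT1	IDO1	CXCL9	CXCL10	HLA-DRA
EIGS	transcribed from source publication	CD3D	IDO1	CIITA	CD3E	CCL5	GZMK	CD2	HLA-DRA	CXCL13	IL2RG	NKG7	HLA-E	CXCR6	LAG3	TAGAP	CXCL10	STAT1	GZMB
CRMA	transcribed from source publication	MAGEA2	MAGEA2B	MAGEA3	MAGEA6	MAGEA12	CSAG1	CSAG2	CSAG3
ESCS	transcribed from source publication	FLNA	EMP3	CALD1	FN1	FOXC2	LOX	FBN1	TNC
TLS	transcribed from source publication	CD79B	CD1D	CCR6	LAT	SKAP1	CETP	EIF1AY	RBP5	PTGDS
Renal-101	transcribed from source publication	CD3G	CD3E	CD8B	THEMIS	TRAT1	GRAP2	CD247	CD2	CD96	PRF1	CD6	IL7R	ITK	GPR18	EOMES	SIT1	NLRC3	CD244	KLRD1	SH2D1A	CCL5	XCL2	CST7	GFI1	KCNA3	PSTPIP1
TIG	transcribed from source publication	CCL5	CD27	CD274	CD276	CD8A	CMKLR1	CXCL9	CXCR6	HLA-DQA1	HLA-DRB1	HLA-E	IDO1	LAG3	NKG7	PDCD1LG2	PSMB10	STAT1	TIGIT
F-TBRS	transcribed from source publication	ACTA2	ACTG2	ADAM12	ADAM19	CNN1	COL4A1	CTGF	CTPS1	RFLNB	FSTL3	HSPB1	IGFBP3	PXDC1	SEMA7A	SH3PXD2A	TAGLN	TNS1	TPM1	TPM2
APM	transcribed from source publication	HLA-A	HLA-B	HLA-C	B2M	TAP1	TAP2	TAPBP
CD8T_MCPcounter	transcribed from source publication	CD8B
IMPRES	transcribed from source publication	PDCD1	CD27	CTLA4	CD40	CD28	CD86	CD80	CD274	CD200	CD276	HAVCR2	VSIR	TNFRSF14	TNFSF4	TNFSF9
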