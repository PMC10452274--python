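high_gene	low_gene
PDCD1	TNFSF4
CD27	PDCD1
CTLA4	TNFSF4
CD40	CD28
CD86	TNFSF4
CD28	CD86
CD80	TNFSF9
CD274	VSIR
CD86	HAVCR2
CD40	CD80
CD28	CD276
CD40	CD274
CD40	PDCD1
TNFRSF14	CD86
CD86	CD200
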