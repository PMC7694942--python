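immune_signature	synthetic stand-in immune signature assembled from canonical immune marker genes; not the published 141-gene list	PTPRC	CD2	CD3D	CD3E	CD3G	CD247	CD8A	CD8B	CD4	IL7R	GZMA	GZMB	GZMK	PRF1	NKG7	KLRB1	KLRD1	CCL5	CXCL9	CXCL10	CD79A	CD79B	MS4A1	IGHM	TNFRSF17	LCK	ZAP70	ITK	SH2D1A	CD27	CD28	ICOS	CTLA4	PDCD1	TIGIT	HLA-DRA	HLA-DPB1	HLA-DQA1	CIITA	AIF1
stromal_signature	synthetic stand-in stromal signature assembled from canonical stromal/matrix marker genes; not the published 141-gene list	COL1A1	COL1A2	COL3A1	COL5A1	COL5A2	COL6A3	COL14A1	FAP	THY1	DCN	LUM	POSTN	FBLN1	FBLN2	MMP2	SPARC	TAGLN	ACTA2	PDGFRA	PDGFRB	FN1	VCAN	BGN	OGN	AEBP1	SFRP2	SFRP4	CTSK	TIMP2	LOX	SERPINF1	MXRA8	OLFML1	ISLR	GREM1	ANGPTL2	CDH11	FGF7	GAS1	EDNRA
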