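macrophage_demo	synthetic placeholder macrophage signature (marker-style gene symbols; not a published list)	CD68	CD163	MRC1	MSR1	CSF1R	ITGAM	MARCO	APOE	C1QA	C1QB
cd8_t_cell_demo	synthetic placeholder CD8 T cell signature (marker-style gene symbols; not a published list)	CD8A	CD8B	GZMB	GZMK	PRF1	IFNG	CD3D	CD3E	NKG7	KLRG1
metabolic_demo	synthetic placeholder metabolic gene list (salvage/nucleotide-metabolism symbols; not the curated 1,321-gene list)	CDA	UCK2	UPP1	NT5E	TYMP	TK1	DCK	CTPS1	UMPS	NME1	RRM1	RRM2	DPYD
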