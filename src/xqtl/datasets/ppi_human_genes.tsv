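# species=human
# units=Mb
# Human homologs (GRCh38) of the mouse PPI QTL genes, as published.
gene_id	symbol	chrom	start	end
ENSG00000136754	ABI1	10	26.75	26.86
ENSG00000077420	APBB1IP	10	26.44	26.57
ENSG00000136750	GAD2	10	26.22	26.30
ENSG00000148459	PDSS1	10	26.70	26.75
ENSG00000148584	A1CF	10	50.80	50.89
ENSG00000171862	PTEN	10	87.86	87.97
ENSG00000188611	ASAH2	10	50.18	50.25
ENSG00000138138	ATAD1	10	87.75	87.84
ENSG00000107789	MINPP1	10	87.50	87.55
ENSG00000198682	PAPSS2	10	87.66	87.75
ENSG00000204147	ASAH2B	10	50.74	50.82
ENSG00000198964	SGMS1	10	50.31	50.63
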