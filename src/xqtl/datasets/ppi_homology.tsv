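# Mouse-human homolog pairs for the PPI QTL genes; Asah2 maps to both
# ASAH2 and ASAH2B (one-to-many).
mouse_gene_id	human_gene_id
ENSMUSG00000058835	ENSG00000136754
ENSMUSG00000026786	ENSG00000077420
ENSMUSG00000026787	ENSG00000136750
ENSMUSG00000026784	ENSG00000148459
ENSMUSG00000052595	ENSG00000148584
ENSMUSG00000013663	ENSG00000171862
ENSMUSG00000024887	ENSG00000188611
ENSMUSG00000024887	ENSG00000204147
ENSMUSG00000013662	ENSG00000138138
ENSMUSG00000024896	ENSG00000107789
ENSMUSG00000024899	ENSG00000198682
ENSMUSG00000040451	ENSG00000198964
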