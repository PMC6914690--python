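# species=mouse
# units=Mb
# Mouse genes (GRCm38) inside the two PPI QTL intervals, as published.
gene_id	symbol	chrom	start	end
ENSMUSG00000058835	Abi1	2	22.94	23.04
ENSMUSG00000026786	Apbb1ip	2	22.77	22.88
ENSMUSG00000026787	Gad2	2	22.62	22.69
ENSMUSG00000026784	Pdss1	2	22.90	22.94
ENSMUSG00000052595	A1cf	19	31.87	31.95
ENSMUSG00000013663	Pten	19	32.76	32.83
ENSMUSG00000024887	Asah2	19	31.98	32.06
ENSMUSG00000013662	Atad1	19	32.67	32.71
ENSMUSG00000024896	Minpp1	19	32.49	32.52
ENSMUSG00000024899	Papss2	19	32.62	32.67
ENSMUSG00000040451	Sgms1	19	32.12	32.39
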