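# Genome-wide significant PPI QTL intervals (mouse, Mb) as published:
# trait 18755 on chromosome 2 (peak LRS 21.4), trait 11428 on chromosome 19
# (peak LRS 19.2).
trait_id	chrom	start_Mb	end_Mb	peak_marker	peak_LRS
18755	2	22	24	rs13476379	21.4
11428	19	31	33	rs6197068	19.2
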