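ID	beta	stats	pvalue	FDR
chr1:70-71	-0.102076	-18.5884	0.0028816	0.0201712
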