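ID	beta	stats	pvalue	FDR
chr1:5-75	0.0138095	0.871614	0.475323	0.475323
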