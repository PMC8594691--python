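ID	beta	stats	pvalue	FDR
chr1:30-31	0.102761	1.8304	0.208675	0.365182
chr1:50-51	8.32667e-18	1.17757e-16	1	1
chr1:60-61	0.23	3.50747	0.0725505	0.169284
chr1:70-71	-0.102076	-18.5884	0.0028816	0.0201712
chr1:80-81	0.02	0.707107	0.552786	0.644917
chr1:90-91	-0.23	-3.50747	0.0725505	0.169284
chr1:100-101	0.04	1.1547	0.367544	0.514562
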