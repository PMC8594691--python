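chrom	start	end	S1	S2	S3	S4
chr1	5	75	0.414286	0.385714	0.466667	0.433333
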