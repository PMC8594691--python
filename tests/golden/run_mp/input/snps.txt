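snp	S1	S2	S3	S4
chr1:14	1	2	2	3
chr1:54	1	1	2	3
chr1:94	1	1	2	3
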