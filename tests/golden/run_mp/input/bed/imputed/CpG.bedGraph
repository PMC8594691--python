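chrom	start	end	S1	S2	S3	S4
chr1	10	11	0.1	0.2	0.3	0.4
chr1	20	21	0.5	0.5	0.5	0.5
chr1	30	31	0.2	0.4	0.6	0.47587
chr1	40	41	0.8	0.6	0.4	0.2
chr1	50	51	0.3	0.1	0.4	0.2
chr1	60	61	0.1	0.1	0.6	0.7
chr1	70	71	0.9	0.8	0.679245	0.6
chr1	80	81	0.2	0.3	0.2	0.3
chr1	90	91	0.7	0.7	0.2	0.1
chr1	100	101	0.4	0.5	0.6	0.5
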