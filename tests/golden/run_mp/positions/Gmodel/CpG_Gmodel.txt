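ID	snp	beta	stats	pvalue	FDR
chr1:10-11	chr1:14	0.15	4.24264	0.0513167	0.144692
chr1:10-11	chr1:54	0.127273	4.04145	0.0561202	0.144692
chr1:10-11	chr1:94	0.127273	4.04145	0.0561202	0.144692
chr1:30-31	chr1:14	0.137935	1.28256	0.328214	0.521281
chr1:30-31	chr1:54	0.107213	1.09521	0.387709	0.550956
chr1:30-31	chr1:94	0.107213	1.09521	0.387709	0.550956
chr1:40-41	chr1:14	-0.3	-4.24264	0.0513167	0.144692
chr1:40-41	chr1:54	-0.254545	-4.04145	0.0561202	0.144692
chr1:40-41	chr1:94	-0.254545	-4.04145	0.0561202	0.144692
chr1:50-51	chr1:14	-0.05	-0.471405	0.683772	0.754368
chr1:50-51	chr1:54	0.0181818	0.19245	0.86516	0.86516
chr1:50-51	chr1:94	0.0181818	0.19245	0.86516	0.86516
chr1:60-61	chr1:14	0.3	1.68034	0.234908	0.422834
chr1:60-61	chr1:54	0.318182	4.375	0.0484773	0.144692
chr1:60-61	chr1:94	0.318182	4.375	0.0484773	0.144692
chr1:70-71	chr1:14	-0.15	-3.48775	0.0732847	0.152207
chr1:70-71	chr1:54	-0.12916	-3.75058	0.0643078	0.144692
chr1:70-71	chr1:94	-0.12916	-3.75058	0.0643078	0.144692
chr1:80-81	chr1:14	0.05	1.41421	0.292893	0.494257
chr1:80-81	chr1:54	0.0181818	0.447214	0.698489	0.754368
chr1:80-81	chr1:94	0.0181818	0.447214	0.698489	0.754368
chr1:90-91	chr1:14	-0.3	-1.68034	0.234908	0.422834
chr1:90-91	chr1:54	-0.318182	-4.375	0.0484773	0.144692
chr1:90-91	chr1:94	-0.318182	-4.375	0.0484773	0.144692
chr1:100-101	chr1:14	0.05	0.816497	0.5	0.675
chr1:100-101	chr1:54	0.0363636	0.666667	0.573599	0.703962
chr1:100-101	chr1:94	0.0363636	0.666667	0.573599	0.703962
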