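locus	chrom	pos	fibroblast	iPS-p31	iPS-p41	HeLa
1p35.1	chr1	32614846	1	1	1	0
10q24.2	chr10	99256369	1	1	1	0
12q12	chr12	43919854	1	1	1	0
13q31.3	chr13	90090934	1	1	1	0
2q22.3	chr2	147700152	0	1	1	0
11q13.3	chr11	70471356	0	1	1	0
15q14	chr15	36348199	0	1	1	0
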