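locus	chrom	pos	HeLa	HeLa-inBLC	fibroblast
11q13.4	chr11	71800891	1	1	0
12p13.31	chr12	8231534	1	1	0
12q23.1	chr12	100854613	1	1	0
17p13.1	chr17	8072100	1	1	0
18p11.21	chr18	15163428	1	1	0
19p12	chr19	21658739	1	1	0
20q13.2	chr20	51642183	1	1	0
1p36.21	chr1	15112068	0	1	0
8q24.22	chr8	133275187	0	1	0
10p15.1	chr10	6263616	0	1	0
12p13.33	chr12	768683	0	1	0
16p11.2	chr16	30785310	0	1	0
16p13.3	chr16	1748182	0	1	0
16q11.2	chr16	46398910	0	1	0
Xq24	chrX	120549077	0	1	0
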