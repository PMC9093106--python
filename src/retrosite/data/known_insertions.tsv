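name	cytoband	chrom	pos
K113	19p12
K20	12q12
K22	13q31.3
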