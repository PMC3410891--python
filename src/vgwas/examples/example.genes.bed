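1	500	1500	GENE_CAUSAL
1	9500	10500	GENE_MID
2	4500	5500	GENE_CHR2
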