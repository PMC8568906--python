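build_a	pos_a	build_b	pos_b
hg19	51159932	hg38	50721504
hg19	51159940	hg38	50721512
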