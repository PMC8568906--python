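>context_wt contig=chr22 build=hg38 start=50721472 cds_start_c=3639 synthetic=true
ACCGCCACAAGGACCGAGGCCGCCACAAGGCGTGGGGGGGGCCGCGCGAGCCACGCGGCCACGCAGGCACCAGAACACGCC
>context_variant contig=chr22 build=hg38 start=50721472 synthetic=true
ACCGCCACAAGGACCGAGGCCGCCACAAGGCGTGGGGGGGGGCCGCGCGAGCCACGCGGCCACGCAGGCACCAGAACACGCC
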