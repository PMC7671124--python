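locus,repeat_motif
MS-03,AC
MS-26,TAA
MS-31,TC
MS-34,TTG
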