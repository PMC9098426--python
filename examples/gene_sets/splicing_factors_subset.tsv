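splicing_factors	SRSF1
splicing_factors	SRSF6
splicing_factors	SF3B1
splicing_factors	U2AF1
splicing_factors	U2AF2
splicing_factors	HNRNPA1
splicing_factors	HNRNPH1
splicing_factors	RBM39
splicing_factors	PRPF8
splicing_factors	SNRNP200
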