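Sustaining proliferative signaling	HRAS
Sustaining proliferative signaling	MCM2
Resisting cell death	BIRC5
Resisting cell death	CD44
Activating invasion and metastasis	CD44
Inducing angiogenesis	VEGFA
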