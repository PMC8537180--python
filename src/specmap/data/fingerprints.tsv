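specificity_label	motif_string
MP	KV[MF]NES
KP	EEAPxx
TP	TRIGPP
oligoNP	FAITQA
T6PP	DQGQDE
subgroup_7	SVSWRQ
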