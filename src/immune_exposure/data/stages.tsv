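stage_label	term_curie
acute	OGMS:9000001
chronic	OGMS:9000002
post	OGMS:9000003
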