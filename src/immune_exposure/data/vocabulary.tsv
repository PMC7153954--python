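category	process_label	term_curie
Administration	Vaccination	OBI:1110101
Administration	Infectious challenge	OBI:1110102
Administration	Transplantation	OBI:1110103
Occurrence of disease	Infectious disease	OBI:1110104
Occurrence of disease	Allergic disease	OBI:1110105
Occurrence of disease	Autoimmune disease	OBI:1110106
Occurrence of disease	Cancer	OBI:1110107
Exposure without disease	Asymptomatic infection	ECTO:9000001
Exposure without disease	Exposure with immune reactivity	ECTO:9000002
Exposure without disease	Documented exposure	ECTO:9000003
Exposure without disease	Exposure to ubiquitous agent	ECTO:9000004
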