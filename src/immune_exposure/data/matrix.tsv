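process_label	material_req	disease_req	stage_req
Vaccination	REQUIRED	ABSENT	ABSENT
Infectious challenge	REQUIRED	OPTIONAL	OPTIONAL
Transplantation	REQUIRED	ABSENT	ABSENT
Infectious disease	REQUIRED	REQUIRED	REQUIRED
Allergic disease	REQUIRED	REQUIRED	REQUIRED
Autoimmune disease	ABSENT	REQUIRED	REQUIRED
Cancer	ABSENT	REQUIRED	REQUIRED
Asymptomatic infection	REQUIRED	ABSENT	ABSENT
Exposure with immune reactivity	REQUIRED	ABSENT	ABSENT
Documented exposure	REQUIRED	ABSENT	ABSENT
Exposure to ubiquitous agent	REQUIRED	ABSENT	ABSENT
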