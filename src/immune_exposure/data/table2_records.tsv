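record_id	source_resource	exposure_process	exposure_material	disease_name	disease_stage	free_text_original
IEDB-1	IEDB	Allergic disease	Penicillin	Penicillin allergy	Chronic	Penicillin allergic subjects
IEDB-2	IEDB	Exposure to ubiquitous agent	Plasmodium falciparum			Healthy donors living in a malaria endemic area
IMMPORT-1	ImmPort	Exposure with immune reactivity	Dengue virus 2			Blood bank donations identified as sero-positive for antibodies against dengue serotype 2
IMMPORT-2	ImmPort	Infectious disease	West Nile virus	West Nile fever	Acute	Subjects with severe West Nile fever
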