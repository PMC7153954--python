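curie	iri	label	source	obsolete	linked_organism_curie
OBI:1110101	http://purl.obolibrary.org/obo/OBI_1110101	vaccination	OBI	false
OBI:1110102	http://purl.obolibrary.org/obo/OBI_1110102	infectious challenge	OBI	false
OBI:1110103	http://purl.obolibrary.org/obo/OBI_1110103	transplantation	OBI	false
OBI:1110104	http://purl.obolibrary.org/obo/OBI_1110104	occurrence of infectious disease	OBI	false
OBI:1110105	http://purl.obolibrary.org/obo/OBI_1110105	occurrence of allergic disease	OBI	false
OBI:1110106	http://purl.obolibrary.org/obo/OBI_1110106	occurrence of autoimmune disease	OBI	false
OBI:1110107	http://purl.obolibrary.org/obo/OBI_1110107	occurrence of cancer	OBI	false
ECTO:9000001	http://purl.obolibrary.org/obo/ECTO_9000001	asymptomatic infection	ECTO	false
ECTO:9000002	http://purl.obolibrary.org/obo/ECTO_9000002	exposure with immune reactivity	ECTO	false
ECTO:9000003	http://purl.obolibrary.org/obo/ECTO_9000003	documented exposure	ECTO	false
ECTO:9000004	http://purl.obolibrary.org/obo/ECTO_9000004	exposure to ubiquitous agent	ECTO	false
OGMS:9000001	http://purl.obolibrary.org/obo/OGMS_9000001	acute	OGMS	false
OGMS:9000002	http://purl.obolibrary.org/obo/OGMS_9000002	chronic	OGMS	false
OGMS:9000003	http://purl.obolibrary.org/obo/OGMS_9000003	post	OGMS	false
NCBITaxon:5833	http://purl.obolibrary.org/obo/NCBITaxon_5833	Plasmodium falciparum	NCBITaxon	false
NCBITaxon:11082	http://purl.obolibrary.org/obo/NCBITaxon_11082	West Nile virus	NCBITaxon	false
NCBITaxon:11060	http://purl.obolibrary.org/obo/NCBITaxon_11060	Dengue virus 2	NCBITaxon	false
NCBITaxon:1773	http://purl.obolibrary.org/obo/NCBITaxon_1773	Mycobacterium tuberculosis	NCBITaxon	false
NCBITaxon:11234	http://purl.obolibrary.org/obo/NCBITaxon_11234	Measles morbillivirus	NCBITaxon	false
NCBITaxon:1280	http://purl.obolibrary.org/obo/NCBITaxon_1280	Staphylococcus aureus	NCBITaxon	false
NCBITaxon:6956	http://purl.obolibrary.org/obo/NCBITaxon_6956	Dermatophagoides pteronyssinus	NCBITaxon	false
NCBITaxon:11676	http://purl.obolibrary.org/obo/NCBITaxon_11676	Human immunodeficiency virus 1	NCBITaxon	false
NCBITaxon:12721	http://purl.obolibrary.org/obo/NCBITaxon_12721	Human immunodeficiency virus	NCBITaxon	true
CHEBI:17334	http://purl.obolibrary.org/obo/CHEBI_17334	Penicillin	ChEBI	false
CHEBI:28112	http://purl.obolibrary.org/obo/CHEBI_28112	Nickel	ChEBI	false
VO:9000001	http://purl.obolibrary.org/obo/VO_9000001	RTS,S malaria vaccine	VO	false	NCBITaxon:5833
VO:9000002	http://purl.obolibrary.org/obo/VO_9000002	measles vaccine	VO	false	NCBITaxon:11234
VO:9000003	http://purl.obolibrary.org/obo/VO_9000003	dengue tetravalent vaccine	VO	false	NCBITaxon:11060
VO:9000004	http://purl.obolibrary.org/obo/VO_9000004	BCG vaccine	VO	false	NCBITaxon:1773
DOID:2365	http://purl.obolibrary.org/obo/DOID_2365	West Nile fever	DOID	false
DOID:0060520	http://purl.obolibrary.org/obo/DOID_0060520	Penicillin allergy	DOID	false
DOID:12365	http://purl.obolibrary.org/obo/DOID_12365	malaria	DOID	false
DOID:8622	http://purl.obolibrary.org/obo/DOID_8622	measles	DOID	false
DOID:12205	http://purl.obolibrary.org/obo/DOID_12205	dengue disease	DOID	false
DOID:9074	http://purl.obolibrary.org/obo/DOID_9074	systemic lupus erythematosus	DOID	false
DOID:7148	http://purl.obolibrary.org/obo/DOID_7148	rheumatoid arthritis	DOID	false
DOID:1612	http://purl.obolibrary.org/obo/DOID_1612	breast cancer	DOID	false
DOID:399	http://purl.obolibrary.org/obo/DOID_399	tuberculosis	DOID	false
DOID:552	http://purl.obolibrary.org/obo/DOID_552	pneumonia	DOID	false
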