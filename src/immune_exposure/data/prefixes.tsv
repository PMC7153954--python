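prefix	namespace
OBI	http://purl.obolibrary.org/obo/OBI_
ECTO	http://purl.obolibrary.org/obo/ECTO_
VO	http://purl.obolibrary.org/obo/VO_
NCBITaxon	http://purl.obolibrary.org/obo/NCBITaxon_
CHEBI	http://purl.obolibrary.org/obo/CHEBI_
DOID	http://purl.obolibrary.org/obo/DOID_
OGMS	http://purl.obolibrary.org/obo/OGMS_
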