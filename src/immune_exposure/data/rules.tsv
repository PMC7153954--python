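rule_id	default_severity	description
IE01	ERROR	Exposure process label is not one of the controlled process types
IE02	ERROR	Field required for this exposure process is absent
IE03	ERROR	Field that must be absent for this exposure process is present
IE04	ERROR	Disease stage entered without a disease name
IE05	ERROR	Disease name entered without a disease stage
IE06	WARNING	Exposure material comes from a source ontology incompatible with the exposure process
IE07	WARNING	Disease stage label is outside the controlled stage vocabulary
IE08	WARNING	Term reference does not resolve in the active term table
IE09	WARNING	Term reference resolves to an obsolete ontology term
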