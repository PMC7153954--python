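# immune-exposure

Validation library and CLI for structured **immune exposure** records —
the metadata that tells you *how* the subjects in an immunological
dataset first met the antigen their antibodies or T cells recognize.
Public immunology repositories (epitope databases, clinical-study data
warehouses) describe that history with four aspects:

* **Exposure Process** — one of 11 controlled types in 3 categories
  (Administration, Occurrence of disease, Exposure without disease);
* **Exposure Material** — the vaccine, organism or chemical
  encountered, bound to an ontology term (VO, NCBI Taxonomy, ChEBI);
* **Disease Name** — the resulting disease (Disease Ontology), if any;
* **Disease Stage** — acute, chronic or post (OGMS).

The value of the model is that the fields validate each other. A
per-process **requirements matrix** says whether material, disease and
stage are Required, Optional or must be absent — an infectious disease
record needs all three; a vaccination record needs a material and must
carry *no* disease or stage — and a symmetric pairing rule ties the
disease and stage together. This package ships that matrix and
vocabulary as data, enforces them as nine rule-coded checks
(IE01–IE09), maintains flat ontology term tables with staleness
diffing, exports record batches as canonical N-Triples, and answers the
cross-resource query "all records whose hosts were exposed to this
pathogen — regardless of disease state, optionally including vaccinated
subjects that were never infected".

It is aimed at data curators and engineers of immunology resources who
need to validate incoming or legacy exposure annotations, and at anyone
harmonizing exposure metadata across repositories.

## Worked example

```python
from immune_exposure import (
    ExposureRecord, canonicalize_record, validate_record, query_by_material,
)

raw = ExposureRecord(
    record_id="STUDY-17",
    source_resource="ImmPort",
    process="vaccination",        # canonicalized to "Vaccination"
    material="VO:9000001",        # RTS,S malaria vaccine
    disease="DOID:12365",         # malaria — but the subject was never ill!
)
rec = canonicalize_record(raw)
for f in validate_record(rec):
    print(f"{f.rule_id} {f.severity} [{f.field}] {f.message}")
```

prints

```
IE03 ERROR [disease] disease must be absent for exposure process 'Vaccination' but holds 'DOID:12365'
```

A vaccination record must
not carry a disease name — that is the matrix cell for Vaccination,
(Required, None, None), doing cross-field work. Dropping the disease
yields an empty finding list.

The same record participates in the pathogen-exposure query: the
vaccine term carries a `linked_organism` bridge to *Plasmodium
falciparum* (`NCBITaxon:5833`), so

```python
query_by_material([rec_fixed, ...], "NCBITaxon:5833", include_vaccines=True)
```

returns its id alongside infection and environmental-exposure records
for the same organism, and omits it when `include_vaccines=False`.

From the shell the same operations are:

```sh
immune-exposure validate records.tsv --out findings.tsv   # exit 0/1/2
immune-exposure export-rdf records.tsv --out records.nt
immune-exposure query records.tsv --material NCBITaxon:5833 --include-vaccines
immune-exposure terms-diff terms_v1.tsv terms_v2.tsv
immune-exposure generate --n 500 --error-rate 0.4 --seed 7 \
    --out batch.tsv --labels-out labels.tsv
immune-exposure vocab-list
```

Exit codes: 0 clean, 1 ERROR-severity findings present, 2 operational
failure (bad input or configuration).

## Layout

```
src/immune_exposure/
  model.py       record schema, controlled vocabulary, requirements matrix
  rules.py       rule catalogue (IE01-IE09), severity configuration
  validation.py  cross-field validation engine + independent pattern oracle
  terms.py       flat ontology term tables: load, resolve, diff, check
  rdfio.py       TSV/JSONL batch I/O, N-Triples export/import, query
  fixtures.py    worked examples + seeded generator with labeled faults
  cli.py         click CLI (validate, export-rdf, query, terms-diff, ...)
  data/          packaged vocabulary, matrix, rules, prefixes, term table
```

See `docs/methods.md` for the model's assumptions, the fault-injection
design and known limitations.
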