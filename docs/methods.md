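# Methods

## The model

An *immune exposure* is the event by which a host's adaptive immune
system first encounters a potential trigger — a vaccination, an
infection, an environmental contact, a transplant. The package models
one exposure event per record with exactly four aspects:

| aspect | content | binding |
|---|---|---|
| Exposure Process | how the encounter happened | controlled vocabulary, 11 types |
| Exposure Material | what was encountered | ontology term (VO vaccine, NCBI Taxonomy organism, ChEBI chemical) |
| Disease Name | the resulting disease, if any | ontology term (Disease Ontology) |
| Disease Stage | temporal phase of that disease | controlled labels bound to OGMS terms |

The 11 process types partition into three categories: Administrations
(Vaccination, Infectious challenge, Transplantation), Occurrences of
disease (Infectious, Allergic, Autoimmune disease, Cancer) and
Exposures without disease (Asymptomatic infection, Exposure with immune
reactivity, Documented exposure, Exposure to ubiquitous agent).

## The requirements matrix

The central validation artifact is a per-process requirements row over
(material, disease, stage), each cell one of REQUIRED / OPTIONAL /
ABSENT. ABSENT is deliberately stronger than "unused": a vaccinated but
healthy subject must not carry a disease name, and the symmetric
disease/stage rule ("no disease ⇒ no stage") shows that absence is
enforced, not merely tolerated. Only one process type, Infectious
challenge, has OPTIONAL cells (disease and stage), because a challenge
may or may not produce disease.

Two cross-field pairing rules couple disease and stage: a stage without
a disease (IE04) and a disease without a stage (IE05) are inconsistent.
They are evaluated only where the matrix does not already force the
outcome — if the disease cell is REQUIRED and the disease is missing,
the record gets one IE02 on the disease, not an additional pairing
finding. One fault, one finding; this also makes the fault-injection
ledger (below) an exact oracle.

Severity defaults: the structural rules IE01–IE05 are ERROR; the
ontology-hygiene rules IE06–IE09 (material source compatibility,
uncontrolled stage label, unknown term, obsolete term) default to
WARNING because source-ontology assignments are in flux (the
environment-exposure types are transitioning between OBI and ECTO) and
the finer compatibility assignments are a curation policy rather than a
hard constraint. All severities are overridable per rule via a
two-column TSV, and `--strict` promotes every WARNING to ERROR.

The default source-compatibility map is: Vaccination → {VO};
Allergic disease → {ChEBI, NCBITaxon}; Autoimmune disease and Cancer →
{} (material is forbidden by the matrix anyway); every other process →
{NCBITaxon}.

## The structural oracle

`expected_pattern_validity` is a deliberately independent re-statement
of the structural rules: a direct lookup that checks each presence flag
against its matrix cell and requires disease and stage to be present or
absent together. It shares no code with `validate_record`. The test
suite enumerates all 11 × 2³ = 88 (process, presence-pattern)
combinations and requires the engine's validity decision (no IE01–IE05
finding) to equal the oracle on every one.

## Term tables

Ontology bindings are flat TSV tables (curie, iri, label, source,
obsolete, linked_organism_curie), standing in for live ontology
services so everything runs desk-scale with no downloads; OWL ingestion
is an extension point, not implemented. Loading rejects duplicate IRIs
and CURIEs that do not expand to their stored IRI under the prefix map.
Resolution prefers exact IRI/CURIE matches; labels match
case-insensitively and a label shared across entries returns an
ambiguity marker rather than a guess. Obsolete terms stay resolvable —
legacy records must remain diagnosable — but references to them are
flagged (IE09). `diff_term_tables` reproduces the periodic-review
workflow: added, removed, relabeled and newly obsolete IRIs between two
table versions, with a term both relabeled and newly obsoleted reported
only as newly obsolete so the four sets stay disjoint.

The packaged mini table carries real NCBI Taxonomy identifiers for the
organisms it names; the process, stage, vaccine and some disease
bindings use illustrative local identifiers inside the real OBO
namespaces (e.g. `OGMS:9000001` for *acute*), chosen not to collide
with curated content. The table is a test- and demo-scale fixture, not
a release of any source ontology. The `linked_organism_curie` column
carries the vaccine→pathogen bridge the cross-resource query needs;
terms without a link simply never match a vaccine-inclusive query.

## RDF export and the cross-resource query

Records triplify to one subject per record
(`base_iri` + percent-encoded record id) with predicates
`hasExposureProcess`, `hasExposureMaterial`, `hasDiseaseName`,
`hasDiseaseStage` and `sourceResource` in a package-defined namespace
(`https://w3id.org/immune-exposure/vocab#`); absent fields emit no
triple, so a record contributes 1 + (number of present aspects)
triples. N-Triples is the canonical serialization because sorting its
lines by (subject, predicate, object) gives byte-reproducible output.
Term references written as CURIEs are expanded to absolute IRIs on
export and compacted back on import; plain labels travel as literals.
Import ignores foreign predicates, reporting them as warnings, and
returns records sorted by id.

`query_by_material` answers the demonstration query — all records whose
hosts were exposed to a given organism — directly over record lists:
disease state is intentionally ignored, and with `include_vaccines` a
material whose `linked_organism_iri` equals the target also matches, so
vaccinated-never-infected subjects are retrieved alongside infections
and environmental exposures. There is no persistent triple store or
SPARQL endpoint; the one demonstrated query shape is implemented
directly.

## Synthetic fixtures

The generator emulates curated exposure batches: it samples a process
type uniformly, satisfies that row of the matrix (drawing the
disease/stage pair jointly so the pairing rule holds by construction),
and draws material and disease terms from the packaged table with
sources compatible with the process. A chosen fraction of records —
`round(n · error_rate)` exactly — receives exactly one injected fault,
sampled from a configurable rule mix (default: uniform over IE02–IE08;
IE01 and IE09 are injectable when named). Infeasible (rule, process)
pairs — e.g. a forbidden-field fault for Infectious challenge, which
has no ABSENT cell — are avoided by sampling the process from the
rule's feasible set, so mislabeled records are never emitted. A single
`random.Random` seeded once per batch drives all choices; output is a
pure function of (spec, tables).

Because each faulty record carries exactly one fault and valid records
are clean by construction, the injection ledger is an exact oracle: the
validator's per-rule finding counts must equal the ledger with 100 %
precision and recall. This is a property of the single-fault design,
not a claim about real repositories — real curation errors co-occur,
field distributions are far from uniform, and free-text noise is absent
here, so passing these tests demonstrates rule correctness, not
expected error rates in production data.

## Numerical and design choices

* Field canonicalization (trim, blank→absent, case-fold process labels
  to canonical casing) is idempotent and required before validation;
  handing the validator a whitespace-only value raises a contract error
  rather than silently passing.
* Findings are ordered by (rule_id, field) and reports are
  byte-reproducible for identical inputs.
* Record identity is caller-supplied, never minted from content —
  source resources own their accessions.
* The stage vocabulary is closed by default to {acute, chronic, post}
  but open for extension via configuration.
* Problem sizes in the test suite and acceptance script (500-record
  fault-recovery batches, 1 000-record round trips) are desk-scale
  choices: large enough that every rule and process type is exercised
  many times, small enough to re-run constantly during development.

## Known limitations

* No OWL-DL reasoning over the published class hierarchy; requirements
  live in data, not axioms.
* No repair or auto-correction; the engine only reports.
* Label-ambiguity handling is conservative (a marker, no guess), which
  means ambiguous labels are skipped by the source-compatibility check.
* The multi-fault interaction behaviour of the validator is exercised
  only incidentally; the generator's ledger guarantee covers
  single-fault records.
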