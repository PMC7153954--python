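"""Core data model for structured immune-exposure records.

An immune exposure — the event by which a host's adaptive immune system
first encounters a trigger — is described by four aspects:

* **Exposure Process** — how the encounter happened, drawn from a closed
  vocabulary of 11 process types in 3 categories (Administration,
  Occurrence of disease, Exposure without disease);
* **Exposure Material** — what was encountered (a vaccine, an organism,
  a chemical), bound to an ontology term;
* **Disease Name** — the resulting disease, if any, bound to an ontology
  term;
* **Disease Stage** — the temporal phase of that disease (acute,
  chronic, post).

Which of the three non-process fields are required, optional or must be
absent depends on the process type; that dependency is captured by the
:class:`RequirementsMatrix`. Both the vocabulary and the matrix ship as
TSV resources inside the package so they are diffable and overridable.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Mapping, Optional

__all__ = [
    "Requirement",
    "OntologyTerm",
    "ExposureProcessType",
    "RequirementRow",
    "RequirementsMatrix",
    "ExposureRecord",
    "ControlledVocabulary",
    "MalformedRecordError",
    "default_vocabulary",
    "default_matrix",
    "default_prefix_map",
    "canonicalize_record",
    "is_absent",
]

#: Categories of exposure process. An *administration* is a direct,
#: controlled first exposure (vaccination, challenge, transplant); an
#: *occurrence of disease* is exposure through a disease process; an
#: *exposure without disease* is an environmental encounter that never
#: produced disease.
CATEGORIES = (
    "Administration",
    "Occurrence of disease",
    "Exposure without disease",
)

SOURCE_KEYS = ("OBI", "ECTO", "VO", "NCBITaxon", "ChEBI", "DOID", "OGMS")


class MalformedRecordError(ValueError):
    """A record violates a structural precondition (e.g. no record_id)."""


class Requirement(enum.Enum):
    """Per-field requirement for a given exposure process type.

    ``ABSENT`` means the field *must not* carry a value: a vaccinated but
    healthy subject has no disease, and the symmetric disease/stage rule
    is enforced, so an unexpected value is an error rather than noise.
    """

    REQUIRED = "REQUIRED"
    OPTIONAL = "OPTIONAL"
    ABSENT = "ABSENT"


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term binding: label, IRI and source ontology.

    ``linked_organism_iri`` bridges product terms to the organism they
    derive from (a vaccine to its pathogen); it is empty when
    inapplicable.
    """

    iri: str
    curie: str
    label: str
    source: str
    obsolete: bool = False
    linked_organism_iri: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.iri:
            raise ValueError("OntologyTerm.iri must be nonempty")
        if not self.label:
            raise ValueError(f"OntologyTerm {self.iri!r} has an empty label")


@dataclass(frozen=True)
class ExposureProcessType:
    label: str
    category: str
    term_curie: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown process category {self.category!r}")


@dataclass(frozen=True)
class RequirementRow:
    """Requirements for (material, disease, stage) under one process type."""

    material: Requirement
    disease: Requirement
    stage: Requirement

    def as_tuple(self) -> tuple[Requirement, Requirement, Requirement]:
        return (self.material, self.disease, self.stage)


@dataclass(frozen=True)
class RequirementsMatrix:
    """Process type -> per-field requirement, one row per process type."""

    rows: Mapping[str, RequirementRow]

    def __getitem__(self, process_label: str) -> RequirementRow:
        return self.rows[process_label]

    def __contains__(self, process_label: str) -> bool:
        return process_label in self.rows

    def __iter__(self) -> Iterator[str]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class ControlledVocabulary:
    """The controlled process-type and disease-stage vocabularies.

    ``stage_labels`` maps each controlled stage label (lower case) to the
    CURIE of its term; the default set is {acute, chronic, post} but the
    set is open for extension via configuration.
    """

    process_types: Mapping[str, ExposureProcessType]
    stage_labels: Mapping[str, str]

    def categories(self) -> set[str]:
        return {p.category for p in self.process_types.values()}

    def types_in_category(self, category: str) -> set[str]:
        return {
            label
            for label, p in self.process_types.items()
            if p.category == category
        }

    def match_process(self, label: str) -> Optional[str]:
        """Case-insensitive lookup returning the canonical casing, or None."""
        needle = label.strip().casefold()
        for canonical in self.process_types:
            if canonical.casefold() == needle:
                return canonical
        return None

    def is_stage_label(self, label: str) -> bool:
        return label.strip().casefold() in self.stage_labels


@dataclass
class ExposureRecord:
    """One subject group's immune-exposure event in the four-aspect model.

    ``material``, ``disease`` and ``stage`` hold a term reference — a
    label, CURIE or absolute IRI — or ``None`` when absent. Identity is
    caller-supplied (source resources own their accessions).
    """

    record_id: str
    source_resource: str = ""
    process: Optional[str] = None
    material: Optional[str] = None
    disease: Optional[str] = None
    stage: Optional[str] = None
    free_text_original: Optional[str] = None

    def field_values(self) -> dict[str, Optional[str]]:
        return {
            "process": self.process,
            "material": self.material,
            "disease": self.disease,
            "stage": self.stage,
        }


def is_absent(value: Optional[str]) -> bool:
    """True when a field value denotes absence (None or blank)."""
    return value is None or value.strip() == ""


# ---------------------------------------------------------------------------
# Packaged resources

def _read_packaged_tsv(name: str) -> list[dict[str, str]]:
    text = resources.files("immune_exposure.data").joinpath(name).read_text(
        encoding="utf-8"
    )
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    return [dict(row) for row in reader]


def default_prefix_map() -> dict[str, str]:
    """CURIE prefix -> IRI namespace for the supported source ontologies."""
    return {
        row["prefix"]: row["namespace"]
        for row in _read_packaged_tsv("prefixes.tsv")
    }


def default_vocabulary() -> ControlledVocabulary:
    """The packaged controlled vocabulary: 11 process types, 3 categories,
    and the stage labels (acute, chronic, post)."""
    process_types = {}
    for row in _read_packaged_tsv("vocabulary.tsv"):
        pt = ExposureProcessType(
            label=row["process_label"],
            category=row["category"],
            term_curie=row["term_curie"],
        )
        process_types[pt.label] = pt
    stage_labels = {
        row["stage_label"].casefold(): row["term_curie"]
        for row in _read_packaged_tsv("stages.tsv")
    }
    return ControlledVocabulary(
        process_types=process_types, stage_labels=stage_labels
    )


def default_matrix() -> RequirementsMatrix:
    """The packaged requirements matrix (one row per process type)."""
    rows = {}
    for row in _read_packaged_tsv("matrix.tsv"):
        rows[row["process_label"]] = RequirementRow(
            material=Requirement(row["material_req"]),
            disease=Requirement(row["disease_req"]),
            stage=Requirement(row["stage_req"]),
        )
    return RequirementsMatrix(rows=rows)


def load_vocabulary(
    vocab_path: str, stages_path: Optional[str] = None
) -> ControlledVocabulary:
    """Load a vocabulary from user-supplied TSVs (same dialects as packaged)."""
    process_types = {}
    with open(vocab_path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            pt = ExposureProcessType(
                label=row["process_label"],
                category=row["category"],
                term_curie=row["term_curie"],
            )
            process_types[pt.label] = pt
    if stages_path is None:
        stage_labels = dict(default_vocabulary().stage_labels)
    else:
        with open(stages_path, encoding="utf-8", newline="") as fh:
            stage_labels = {
                row["stage_label"].casefold(): row["term_curie"]
                for row in csv.DictReader(fh, delimiter="\t")
            }
    return ControlledVocabulary(
        process_types=process_types, stage_labels=stage_labels
    )


def load_matrix(path: str) -> RequirementsMatrix:
    rows = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows[row["process_label"]] = RequirementRow(
                material=Requirement(row["material_req"]),
                disease=Requirement(row["disease_req"]),
                stage=Requirement(row["stage_req"]),
            )
    return RequirementsMatrix(rows=rows)


# ---------------------------------------------------------------------------
# Canonicalization

def _clean(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    value = value.strip()
    return value or None


def canonicalize_record(
    raw_record: ExposureRecord, vocabulary: Optional[ControlledVocabulary] = None
) -> ExposureRecord:
    """Return the canonical form of a record.

    Trims surrounding whitespace, maps empty strings to absence, and
    resolves the process label case-insensitively to its canonical
    casing. Unknown process labels are left untouched (the validation
    engine flags them). Idempotent.
    """
    if not raw_record.record_id or not raw_record.record_id.strip():
        raise MalformedRecordError("record without a record_id")
    if vocabulary is None:
        vocabulary = default_vocabulary()
    process = _clean(raw_record.process)
    if process is not None:
        canonical = vocabulary.match_process(process)
        if canonical is not None:
            process = canonical
    return replace(
        raw_record,
        record_id=raw_record.record_id.strip(),
        source_resource=(raw_record.source_resource or "").strip(),
        process=process,
        material=_clean(raw_record.material),
        disease=_clean(raw_record.disease),
        stage=_clean(raw_record.stage),
        free_text_original=_clean(raw_record.free_text_original),
    )


def canonicalize_batch(
    records: Iterable[ExposureRecord],
    vocabulary: Optional[ControlledVocabulary] = None,
) -> list[ExposureRecord]:
    if vocabulary is None:
        vocabulary = default_vocabulary()
    return [canonicalize_record(r, vocabulary) for r in records]
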