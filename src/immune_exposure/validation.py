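"""Cross-field validation of immune-exposure records.

The requirements matrix says, per exposure process type, whether the
material, disease and stage fields are required, optional or must be
absent. Two further cross-field rules couple disease and stage: a stage
without a disease, or a disease without a stage, is inconsistent. On
top of the structural rules sit ontology-binding checks: the material's
source ontology must fit the process (a vaccine for a vaccination, an
organism for an infection), stage labels must come from the controlled
stage vocabulary, and every term reference must resolve to a live term.

Rules:

====== ===========================================================
IE01   unknown exposure process type
IE02   required field absent
IE03   field present where the matrix demands absence
IE04   stage entered without a disease
IE05   disease entered without a stage
IE06   material source ontology incompatible with the process
IE07   stage label outside the controlled stage vocabulary
IE08   term reference unknown in the term table
IE09   term reference obsolete
====== ===========================================================

The pairing rules IE04/IE05 fire only where the matrix does not already
force the outcome, so a single fault yields a single finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .model import (
    ControlledVocabulary,
    ExposureRecord,
    Requirement,
    RequirementsMatrix,
    default_matrix,
    default_vocabulary,
    is_absent,
)
from .rules import ERROR, Finding, RuleConfig
from .terms import (
    TermTable,
    check_record_terms,
    default_term_table,
    looks_like_curie,
    looks_like_iri,
    resolve,
)
from .model import OntologyTerm

__all__ = [
    "SourceCompatibilityMap",
    "ValidationReport",
    "NotCanonicalError",
    "DuplicateRecordError",
    "UnknownProcessError",
    "validate_record",
    "validate_batch",
    "expected_pattern_validity",
]


class NotCanonicalError(ValueError):
    """validate_record was handed a record that skipped canonicalization."""


class DuplicateRecordError(ValueError):
    """A batch contains the same record_id twice."""


class UnknownProcessError(KeyError):
    """A process label has no row in the requirements matrix."""


@dataclass(frozen=True)
class SourceCompatibilityMap:
    """Process type -> acceptable source-ontology keys for the material.

    The default reflects the ontology division of labour: vaccines come
    from the Vaccine Ontology, organisms from NCBI Taxonomy, allergens
    from ChEBI (chemicals) or NCBI Taxonomy (organisms). Processes whose
    material must be absent carry an empty set (the matrix already
    forbids the field).
    """

    rows: Mapping[str, frozenset[str]]

    @classmethod
    def default(cls) -> "SourceCompatibilityMap":
        taxon = frozenset({"NCBITaxon"})
        return cls(
            rows={
                "Vaccination": frozenset({"VO"}),
                "Infectious challenge": taxon,
                "Transplantation": taxon,
                "Infectious disease": taxon,
                "Allergic disease": frozenset({"ChEBI", "NCBITaxon"}),
                "Autoimmune disease": frozenset(),
                "Cancer": frozenset(),
                "Asymptomatic infection": taxon,
                "Exposure with immune reactivity": taxon,
                "Documented exposure": taxon,
                "Exposure to ubiquitous agent": taxon,
            }
        )


@dataclass(frozen=True)
class ValidationReport:
    """Aggregated findings over a batch of records."""

    findings: tuple[Finding, ...]
    n_records: int
    n_valid: int
    per_rule_counts: Mapping[str, int]

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == ERROR]


def _require_canonical(record: ExposureRecord) -> None:
    for name in ("process", "material", "disease", "stage"):
        value = getattr(record, name)
        if value is not None and (value.strip() != value or value.strip() == ""):
            raise NotCanonicalError(
                f"record {record.record_id!r}: field {name} holds "
                f"{value!r}; canonicalize records before validation"
            )


def _matrix_findings(
    record: ExposureRecord,
    row,
    config: RuleConfig,
) -> list[Finding]:
    findings = []
    cells = {
        "material": row.material,
        "disease": row.disease,
        "stage": row.stage,
    }
    for fld, cell in cells.items():
        present = not is_absent(getattr(record, fld))
        if cell is Requirement.REQUIRED and not present:
            findings.append(
                Finding(
                    rule_id="IE02",
                    field=fld,
                    record_id=record.record_id,
                    severity=config.severity("IE02"),
                    message=(
                        f"{fld} is required for exposure process "
                        f"{record.process!r} but is absent"
                    ),
                )
            )
        elif cell is Requirement.ABSENT and present:
            findings.append(
                Finding(
                    rule_id="IE03",
                    field=fld,
                    record_id=record.record_id,
                    severity=config.severity("IE03"),
                    message=(
                        f"{fld} must be absent for exposure process "
                        f"{record.process!r} but holds "
                        f"{getattr(record, fld)!r}"
                    ),
                )
            )
    return findings


def _pairing_findings(
    record: ExposureRecord,
    disease_cell: Requirement,
    stage_cell: Requirement,
    config: RuleConfig,
) -> list[Finding]:
    """Disease/stage pairing (IE04/IE05), suppressed where the matrix has
    already attributed the same inconsistency to a cell violation."""
    findings = []
    disease_present = not is_absent(record.disease)
    stage_present = not is_absent(record.stage)
    if (
        stage_present
        and not disease_present
        and disease_cell is not Requirement.REQUIRED
        and stage_cell is not Requirement.ABSENT
    ):
        findings.append(
            Finding(
                rule_id="IE04",
                field="cross-field",
                record_id=record.record_id,
                severity=config.severity("IE04"),
                message="disease stage entered without a disease name",
            )
        )
    if (
        disease_present
        and not stage_present
        and stage_cell is not Requirement.REQUIRED
        and disease_cell is not Requirement.ABSENT
    ):
        findings.append(
            Finding(
                rule_id="IE05",
                field="cross-field",
                record_id=record.record_id,
                severity=config.severity("IE05"),
                message="disease name entered without a disease stage",
            )
        )
    return findings


def validate_record(
    record: ExposureRecord,
    matrix: Optional[RequirementsMatrix] = None,
    vocabulary: Optional[ControlledVocabulary] = None,
    compat: Optional[SourceCompatibilityMap] = None,
    term_table: Optional[TermTable] = None,
    config: Optional[RuleConfig] = None,
) -> list[Finding]:
    """All findings for one canonicalized record, ordered by
    (rule_id, field) for reproducible reports."""
    if matrix is None:
        matrix = default_matrix()
    if vocabulary is None:
        vocabulary = default_vocabulary()
    if compat is None:
        compat = SourceCompatibilityMap.default()
    if term_table is None:
        term_table = default_term_table()
    if config is None:
        config = RuleConfig.default()
    _require_canonical(record)

    findings: list[Finding] = []
    process_known = record.process is not None and record.process in matrix.rows

    if is_absent(record.process):
        findings.append(
            Finding(
                rule_id="IE02",
                field="process",
                record_id=record.record_id,
                severity=config.severity("IE02"),
                message="exposure process is absent",
            )
        )
    elif not process_known:
        findings.append(
            Finding(
                rule_id="IE01",
                field="process",
                record_id=record.record_id,
                severity=config.severity("IE01"),
                message=(
                    f"unknown exposure process type {record.process!r}"
                ),
            )
        )

    if process_known:
        row = matrix[record.process]
        findings.extend(_matrix_findings(record, row, config))
        findings.extend(
            _pairing_findings(record, row.disease, row.stage, config)
        )
    else:
        # no matrix row: the pairing rule still applies on its own
        findings.extend(
            _pairing_findings(
                record, Requirement.OPTIONAL, Requirement.OPTIONAL, config
            )
        )

    # IE06: material source ontology vs process type
    if (
        process_known
        and not is_absent(record.material)
        and matrix[record.process].material is not Requirement.ABSENT
    ):
        allowed = compat.rows.get(record.process)
        if allowed:
            resolved = resolve(record.material, term_table)
            if isinstance(resolved, OntologyTerm) and resolved.source not in allowed:
                findings.append(
                    Finding(
                        rule_id="IE06",
                        field="material",
                        record_id=record.record_id,
                        severity=config.severity("IE06"),
                        message=(
                            f"material {record.material!r} comes from "
                            f"{resolved.source}, not an accepted source "
                            f"({', '.join(sorted(allowed))}) for process "
                            f"{record.process!r}"
                        ),
                    )
                )

    # IE07: stage label outside the controlled stage vocabulary
    if not is_absent(record.stage) and not (
        looks_like_iri(record.stage) or looks_like_curie(record.stage)
    ):
        if not vocabulary.is_stage_label(record.stage):
            findings.append(
                Finding(
                    rule_id="IE07",
                    field="stage",
                    record_id=record.record_id,
                    severity=config.severity("IE07"),
                    message=(
                        f"stage {record.stage!r} is not a controlled stage "
                        f"label ({', '.join(sorted(vocabulary.stage_labels))})"
                    ),
                )
            )

    # IE08/IE09: term references against the term table
    findings.extend(check_record_terms([record], term_table, config))

    return sorted(findings, key=lambda f: (f.rule_id, f.field))


def validate_batch(
    records: Iterable[ExposureRecord],
    matrix: Optional[RequirementsMatrix] = None,
    vocabulary: Optional[ControlledVocabulary] = None,
    compat: Optional[SourceCompatibilityMap] = None,
    term_table: Optional[TermTable] = None,
    config: Optional[RuleConfig] = None,
) -> ValidationReport:
    """Validate a batch of canonicalized records.

    Per-record results are independent of batch order. Duplicate
    record_ids raise :class:`DuplicateRecordError`.
    """
    records = list(records)
    seen: set[str] = set()
    for r in records:
        if r.record_id in seen:
            raise DuplicateRecordError(
                f"record_id {r.record_id!r} appears more than once"
            )
        seen.add(r.record_id)

    all_findings: list[Finding] = []
    n_valid = 0
    per_rule: dict[str, int] = {}
    for r in records:
        fs = validate_record(r, matrix, vocabulary, compat, term_table, config)
        all_findings.extend(fs)
        if not any(f.severity == ERROR for f in fs):
            n_valid += 1
        for f in fs:
            per_rule[f.rule_id] = per_rule.get(f.rule_id, 0) + 1
    return ValidationReport(
        findings=tuple(all_findings),
        n_records=len(records),
        n_valid=n_valid,
        per_rule_counts=per_rule,
    )


def expected_pattern_validity(
    process_label: str,
    material_present: bool,
    disease_present: bool,
    stage_present: bool,
    matrix: Optional[RequirementsMatrix] = None,
) -> bool:
    """Whether a presence pattern is structurally valid, by direct table
    lookup.

    Independent of :func:`validate_record`'s code path, this is the
    brute-force oracle for the structural rules: each presence flag must
    satisfy its matrix cell (REQUIRED -> present, ABSENT -> absent,
    OPTIONAL -> either) and the disease and stage must be present or
    absent together.
    """
    if matrix is None:
        matrix = default_matrix()
    if process_label not in matrix.rows:
        raise UnknownProcessError(process_label)
    row = matrix[process_label]
    for cell, present in (
        (row.material, material_present),
        (row.disease, disease_present),
        (row.stage, stage_present),
    ):
        if cell is Requirement.REQUIRED and not present:
            return False
        if cell is Requirement.ABSENT and present:
            return False
    return disease_present == stage_present
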