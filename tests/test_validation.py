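"""Cross-field validation rules against the requirements matrix."""

from itertools import product

import pytest

from immune_exposure import (
    DuplicateRecordError,
    ExposureRecord,
    FixtureSpec,
    NotCanonicalError,
    RuleConfig,
    expected_pattern_validity,
    generate_records,
    validate_batch,
    validate_record,
)
from immune_exposure.validation import UnknownProcessError

STRUCTURAL = ("IE01", "IE02", "IE03", "IE04", "IE05")


def _record(process, material=None, disease=None, stage=None, rid="r1"):
    return ExposureRecord(
        record_id=rid,
        source_resource="IEDB",
        process=process,
        material=material,
        disease=disease,
        stage=stage,
    )


def _pattern_record(process, m, d, s):
    return _record(
        process,
        material="NCBITaxon:5833" if m else None,
        disease="DOID:12365" if d else None,
        stage="acute" if s else None,
    )


class TestSingleRecordRules:
    def test_infection_with_disease_and_stage_is_clean(self):
        rec = _record(
            "Infectious disease", "West Nile virus", "West Nile fever", "Acute"
        )
        assert validate_record(rec) == []

    def test_endemic_exposure_without_disease_is_clean(self):
        rec = _record("Exposure to ubiquitous agent", "Plasmodium falciparum")
        assert validate_record(rec) == []

    def test_vaccination_with_disease_triggers_forbidden_field(self):
        rec = _record("Vaccination", "VO:9000001", disease="DOID:12365")
        rules = {(f.rule_id, f.field) for f in validate_record(rec)}
        assert ("IE03", "disease") in rules

    def test_challenge_disease_without_stage_triggers_pairing(self):
        rec = _record("Infectious challenge", "NCBITaxon:5833", "DOID:12365")
        assert {f.rule_id for f in validate_record(rec)} == {"IE05"}

    def test_challenge_stage_without_disease_triggers_pairing(self):
        rec = _record("Infectious challenge", "NCBITaxon:5833", stage="acute")
        assert {f.rule_id for f in validate_record(rec)} == {"IE04"}

    def test_empty_record_flags_the_process(self):
        findings = validate_record(ExposureRecord(record_id="r1"))
        assert any(
            f.rule_id in ("IE01", "IE02") and f.field == "process"
            for f in findings
        )

    def test_unknown_process_type(self):
        findings = validate_record(_record("Spontaneous exposure", "NCBITaxon:5833"))
        assert [f.rule_id for f in findings] == ["IE01"]

    def test_incompatible_material_source_is_warned(self):
        # an organism where a vaccine term is expected
        rec = _record("Vaccination", "NCBITaxon:5833")
        findings = validate_record(rec)
        assert [f.rule_id for f in findings] == ["IE06"]
        assert findings[0].severity == "WARNING"

    def test_uncontrolled_stage_label(self):
        rec = _record(
            "Infectious disease", "NCBITaxon:5833", "DOID:12365", "terminal"
        )
        assert [f.rule_id for f in validate_record(rec)] == ["IE07"]

    def test_unknown_and_obsolete_terms(self):
        unknown = _record("Infectious disease", "NCBITaxon:42424242", "DOID:12365", "acute")
        assert [f.rule_id for f in validate_record(unknown)] == ["IE08"]
        obsolete = _record("Infectious disease", "NCBITaxon:12721", "DOID:12365", "acute")
        assert [f.rule_id for f in validate_record(obsolete)] == ["IE09"]

    def test_non_canonical_input_is_a_contract_violation(self):
        with pytest.raises(NotCanonicalError):
            validate_record(_record("Vaccination", "  "))

    def test_findings_sorted_and_deterministic(self):
        rec = _record("Cancer", "NCBITaxon:42424242", stage="weird")
        first = validate_record(rec)
        second = validate_record(rec)
        assert first == second
        assert [(f.rule_id, f.field) for f in first] == sorted(
            (f.rule_id, f.field) for f in first
        )

    def test_severity_overrides_and_strict_mode(self):
        rec = _record("Vaccination", "NCBITaxon:5833")
        strict = validate_record(rec, config=RuleConfig.default().strict())
        assert [f.severity for f in strict] == ["ERROR"]
        demoted = RuleConfig(
            severities={**RuleConfig.default().severities, "IE06": "WARNING"}
        )
        assert validate_record(rec, config=demoted)[0].severity == "WARNING"


class TestPatternOracle:
    def test_vaccination_material_only_is_valid(self, matrix):
        assert expected_pattern_validity("Vaccination", True, False, False, matrix)

    def test_cancer_with_material_is_invalid(self, matrix):
        assert not expected_pattern_validity("Cancer", True, True, True, matrix)

    def test_unknown_process_raises(self, matrix):
        with pytest.raises(UnknownProcessError):
            expected_pattern_validity("Teleportation", True, True, True, matrix)

    def test_engine_matches_oracle_on_all_88_patterns(self, matrix):
        """Exhaustive enumeration: the engine's structural validity
        decision equals the independent table-lookup oracle."""
        for process, flags in product(
            sorted(matrix.rows), product((False, True), repeat=3)
        ):
            rec = _pattern_record(process, *flags)
            findings = validate_record(rec)
            engine_valid = not any(f.rule_id in STRUCTURAL for f in findings)
            assert engine_valid == expected_pattern_validity(
                process, *flags, matrix=matrix
            ), (process, flags)

    def test_pairing_rules_never_cooccur(self, matrix):
        for process, flags in product(
            sorted(matrix.rows), product((False, True), repeat=3)
        ):
            rules = {
                f.rule_id for f in validate_record(_pattern_record(process, *flags))
            }
            assert not ({"IE04", "IE05"} <= rules), (process, flags)


class TestBatch:
    def test_table2_records_all_validate(self, table2):
        report = validate_batch(table2)
        assert report.n_records == 4
        assert report.n_valid == 4
        assert report.findings == ()

    def test_empty_batch(self):
        report = validate_batch([])
        assert (report.n_records, report.n_valid, report.findings) == (0, 0, ())

    def test_duplicate_record_ids_rejected(self):
        recs = [_record("Vaccination", "VO:9000001", rid="x")] * 2
        with pytest.raises(DuplicateRecordError):
            validate_batch(recs)

    def test_per_rule_counts_sum_to_findings(self):
        labeled = generate_records(FixtureSpec(n=120, error_rate=0.5, seed=11))
        report = validate_batch([lr.record for lr in labeled])
        assert sum(report.per_rule_counts.values()) == len(report.findings)
        assert report.n_valid <= report.n_records

    def test_order_independence(self):
        labeled = generate_records(FixtureSpec(n=40, error_rate=0.5, seed=5))
        recs = [lr.record for lr in labeled]
        forward = validate_batch(recs)
        backward = validate_batch(recs[::-1])
        assert sorted(forward.findings) == sorted(backward.findings)
        assert forward.n_valid == backward.n_valid


class TestMonotonicity:
    def test_removing_single_fault_restores_validity(self, matrix):
        """For single-fault records on matrix cells, clearing the
        offending field (or restoring a required one) flips the record
        back to fully clean."""
        labeled = generate_records(FixtureSpec(n=200, error_rate=1.0, seed=13))
        for lr in labeled:
            rule = next(iter(lr.injected_rules))
            if rule != "IE03":
                continue
            findings = validate_record(lr.record)
            assert len(findings) == 1
            fixed = ExposureRecord(**vars(lr.record))
            setattr(fixed, findings[0].field, None)
            assert validate_record(fixed) == []

    def test_adding_forbidden_field_never_removes_findings(self, matrix):
        from immune_exposure import Requirement

        labeled = generate_records(FixtureSpec(n=60, error_rate=0.0, seed=21))
        for lr in labeled:
            row = matrix[lr.record.process]
            before = set()
            for fld, cell in zip(
                ("material", "disease", "stage"), row.as_tuple()
            ):
                if cell is Requirement.ABSENT:
                    worse = ExposureRecord(**vars(lr.record))
                    setattr(worse, fld, "DOID:12365" if fld != "stage" else "acute")
                    after = {(f.rule_id, f.field) for f in validate_record(worse)}
                    assert before <= after and after
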