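"""Synthetic record batches with labeled error injection.

The generator builds structurally valid records by construction —
sample a process type uniformly, satisfy its requirements row, draw
material and disease terms from the packaged term table with sources
compatible with the process — and then injects exactly one labeled
fault into a chosen fraction of records. Because every faulty record
carries exactly one fault, the injection ledger is an unambiguous
oracle for the validation engine: grouped by rule, the validator's
findings must equal the ledger exactly.

Also packaged here are the four worked example records (one allergic
subject group, one endemic-area exposure, one sero-positive blood-bank
cohort, one acute infection) used throughout the tests and docs.

Distributions are uniform; no attempt is made to mimic the field
distributions or free-text noise of real repositories.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

from .model import (
    ControlledVocabulary,
    ExposureRecord,
    Requirement,
    RequirementsMatrix,
    canonicalize_batch,
    default_matrix,
    default_vocabulary,
)
from .rdfio import read_records
from .terms import TermTable, default_term_table
from .validation import SourceCompatibilityMap

__all__ = [
    "FixtureSpec",
    "LabeledRecord",
    "INJECTABLE_RULES",
    "table2_fixtures",
    "generate_records",
    "write_labels",
]

#: Rules the generator can inject by default (uniform mix). IE01 and
#: IE09 are also injectable when named explicitly in ``rule_mix``.
INJECTABLE_RULES = ("IE02", "IE03", "IE04", "IE05", "IE06", "IE07", "IE08")

_SOURCES = ("EuPathDB", "IEDB", "ImmPort")
_UNKNOWN_PROCESS = "Unrecognized process"
_UNKNOWN_STAGE = "indeterminate"
_UNKNOWN_CURIE = "NCBITaxon:999999999"


@dataclass(frozen=True)
class FixtureSpec:
    """How many records to generate, how many get one injected fault,
    and with which rule mix."""

    n: int
    error_rate: float = 0.0
    seed: int = 0
    rule_mix: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.rule_mix is not None:
            if any(w < 0 for w in self.rule_mix.values()):
                raise ValueError("rule_mix weights must be nonnegative")
            if not any(self.rule_mix.values()):
                raise ValueError("rule_mix weights must not all be zero")


@dataclass(frozen=True)
class LabeledRecord:
    """A generated record together with its injected-fault ledger entry
    (empty for valid records)."""

    record: ExposureRecord
    injected_rules: frozenset[str] = field(default_factory=frozenset)


def table2_fixtures() -> list[ExposureRecord]:
    """The four packaged worked-example records, canonicalized, with
    every term reference resolvable in the packaged term table."""
    ref = resources.files("immune_exposure.data").joinpath("table2_records.tsv")
    with resources.as_file(ref) as path:
        records = read_records(str(path), dialect="tsv")
    return canonicalize_batch(records)


def _pools(term_table: TermTable) -> dict[str, list]:
    """Deterministic candidate term lists per source key."""
    pools: dict[str, list] = {}
    for term in sorted(term_table.terms.values(), key=lambda t: t.curie):
        if term.source in ("OBI", "ECTO", "OGMS"):
            continue  # process/stage bindings, not record field values
        key = "obsolete" if term.obsolete else term.source
        pools.setdefault(key, []).append(term)
    return pools


def _material_pool(
    process: str,
    compat: SourceCompatibilityMap,
    pools: dict[str, list],
    compatible: bool,
) -> list:
    allowed = compat.rows.get(process, frozenset())
    pool = []
    for source in sorted(pools):
        if source in ("obsolete", "DOID"):
            continue
        if (source in allowed) == compatible:
            pool.extend(pools[source])
    return pool


def _build_valid(
    process: str,
    rng: random.Random,
    matrix: RequirementsMatrix,
    compat: SourceCompatibilityMap,
    pools: dict[str, list],
    pair_present: Optional[bool] = None,
) -> ExposureRecord:
    row = matrix[process]
    material = disease = stage = None
    if row.material is Requirement.REQUIRED or (
        row.material is Requirement.OPTIONAL and rng.random() < 0.5
    ):
        material = rng.choice(_material_pool(process, compat, pools, True)).curie
    # disease and stage are drawn jointly so the pairing rule holds
    if row.disease is Requirement.REQUIRED:
        pair = True
    elif row.disease is Requirement.ABSENT:
        pair = False
    else:
        pair = rng.random() < 0.5 if pair_present is None else pair_present
    if pair:
        disease = rng.choice(pools["DOID"]).curie
        stage = rng.choice(("acute", "chronic", "post"))
    return ExposureRecord(
        record_id="",  # assigned by the caller
        source_resource=rng.choice(_SOURCES),
        process=process,
        material=material,
        disease=disease,
        stage=stage,
    )


def _feasible_processes(
    rule: str,
    matrix: RequirementsMatrix,
    compat: SourceCompatibilityMap,
    pools: dict[str, list],
) -> list[str]:
    out = []
    for process in sorted(matrix.rows):
        row = matrix[process]
        cells = row.as_tuple()
        if rule in ("IE01",):
            ok = True
        elif rule == "IE02":
            ok = Requirement.REQUIRED in cells
        elif rule == "IE03":
            ok = Requirement.ABSENT in cells
        elif rule in ("IE04", "IE05"):
            ok = (
                row.disease is Requirement.OPTIONAL
                and row.stage is Requirement.OPTIONAL
            )
        elif rule == "IE06":
            ok = (
                row.material is Requirement.REQUIRED
                and bool(compat.rows.get(process))
                and bool(_material_pool(process, compat, pools, False))
            )
        elif rule == "IE07":
            ok = row.stage is not Requirement.ABSENT
        elif rule == "IE08":
            ok = row.material is Requirement.REQUIRED
        elif rule == "IE09":
            ok = (
                row.material is Requirement.REQUIRED
                and bool(pools.get("obsolete"))
                and any(
                    t.source in compat.rows.get(process, frozenset())
                    for t in pools["obsolete"]
                )
            )
        else:
            raise ValueError(f"cannot inject rule {rule!r}")
        if ok:
            out.append(process)
    return out


def _inject(
    rule: str,
    process: str,
    rng: random.Random,
    matrix: RequirementsMatrix,
    compat: SourceCompatibilityMap,
    pools: dict[str, list],
) -> ExposureRecord:
    """A record for ``process`` carrying exactly the fault ``rule``."""
    row = matrix[process]
    if rule == "IE04":
        record = _build_valid(process, rng, matrix, compat, pools, pair_present=False)
        record.stage = rng.choice(("acute", "chronic", "post"))
        return record
    if rule == "IE05":
        record = _build_valid(process, rng, matrix, compat, pools, pair_present=True)
        record.stage = None
        return record
    if rule == "IE07":
        record = _build_valid(
            process,
            rng,
            matrix,
            compat,
            pools,
            pair_present=True if row.stage is Requirement.OPTIONAL else None,
        )
        record.stage = _UNKNOWN_STAGE
        return record

    record = _build_valid(process, rng, matrix, compat, pools)
    if rule == "IE01":
        record.process = _UNKNOWN_PROCESS
    elif rule == "IE02":
        fld = rng.choice(
            [
                f
                for f, cell in zip(("material", "disease", "stage"), row.as_tuple())
                if cell is Requirement.REQUIRED
            ]
        )
        setattr(record, fld, None)
    elif rule == "IE03":
        fld = rng.choice(
            [
                f
                for f, cell in zip(("material", "disease", "stage"), row.as_tuple())
                if cell is Requirement.ABSENT
            ]
        )
        if fld == "material":
            record.material = rng.choice(
                _material_pool("Infectious disease", compat, pools, True)
            ).curie
        elif fld == "disease":
            record.disease = rng.choice(pools["DOID"]).curie
        else:
            record.stage = rng.choice(("acute", "chronic", "post"))
    elif rule == "IE06":
        record.material = rng.choice(
            _material_pool(process, compat, pools, False)
        ).curie
    elif rule == "IE08":
        record.material = _UNKNOWN_CURIE
    elif rule == "IE09":
        allowed = compat.rows.get(process, frozenset())
        candidates = [t for t in pools["obsolete"] if t.source in allowed]
        record.material = rng.choice(candidates).curie
    return record


def generate_records(
    spec: FixtureSpec,
    vocabulary: Optional[ControlledVocabulary] = None,
    matrix: Optional[RequirementsMatrix] = None,
    term_table: Optional[TermTable] = None,
    compat: Optional[SourceCompatibilityMap] = None,
) -> list[LabeledRecord]:
    """Generate ``spec.n`` records; ``round(n * error_rate)`` of them
    receive exactly one injected fault, drawn from ``rule_mix``.

    A single :class:`random.Random` seeded from ``spec.seed`` drives all
    choices, so output is a pure function of (spec, tables). When an
    injected rule is infeasible for a sampled process (e.g. a forbidden
    field for a process with no ABSENT cell), the process is resampled
    from the feasible set — mislabeled records are never emitted.
    """
    if vocabulary is None:
        vocabulary = default_vocabulary()
    if matrix is None:
        matrix = default_matrix()
    if term_table is None:
        term_table = default_term_table()
    if compat is None:
        compat = SourceCompatibilityMap.default()
    pools = _pools(term_table)
    rng = random.Random(spec.seed)

    mix = dict(spec.rule_mix) if spec.rule_mix else {r: 1.0 for r in INJECTABLE_RULES}
    mix_rules = sorted(r for r, w in mix.items() if w > 0)
    mix_weights = [mix[r] for r in mix_rules]
    feasible = {
        r: _feasible_processes(r, matrix, compat, pools) for r in mix_rules
    }
    for r in mix_rules:
        if not feasible[r]:
            raise ValueError(f"rule {r} is not injectable under these tables")

    n_faulty = int(round(spec.n * spec.error_rate))
    faulty_indices = set(rng.sample(range(spec.n), n_faulty)) if spec.n else set()

    processes = sorted(matrix.rows)
    out: list[LabeledRecord] = []
    for i in range(spec.n):
        record_id = f"SYN-{i:05d}"
        if i in faulty_indices:
            rule = rng.choices(mix_rules, weights=mix_weights, k=1)[0]
            process = rng.choice(feasible[rule])
            record = _inject(rule, process, rng, matrix, compat, pools)
            record.record_id = record_id
            out.append(
                LabeledRecord(record=record, injected_rules=frozenset({rule}))
            )
        else:
            record = _build_valid(
                rng.choice(processes), rng, matrix, compat, pools
            )
            record.record_id = record_id
            out.append(LabeledRecord(record=record))
    return out


def write_labels(labeled: Sequence[LabeledRecord], path: str) -> None:
    """Sidecar ledger TSV (record_id, injected_rule; one row per fault)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("record_id\tinjected_rule\n")
        for lr in labeled:
            for rule in sorted(lr.injected_rules):
                fh.write(f"{lr.record.record_id}\t{rule}\n")
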