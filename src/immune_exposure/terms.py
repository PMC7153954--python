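"""Flat ontology term tables: loading, resolution and version diffing.

Data resources that bind records to ontology terms store the term IRI
and periodically re-check it against the source ontology, because terms
get relabeled or retired (obsoleted) between releases. This module
reproduces that maintenance workflow at desk scale on flat TSV tables
(columns: curie, iri, label, source, obsolete, linked_organism_curie)
instead of live ontology services or OWL files.

Obsolete terms remain resolvable — legacy records must stay diagnosable
— but references to them are flagged (rule IE09).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Union

from .model import ExposureRecord, OntologyTerm, default_prefix_map, is_absent
from .rules import Finding, RuleConfig

__all__ = [
    "TermTable",
    "TermDiff",
    "NotFound",
    "NOT_FOUND",
    "Ambiguity",
    "TermTableError",
    "load_term_table",
    "default_term_table",
    "resolve",
    "diff_term_tables",
    "check_record_terms",
    "expand_curie",
    "compact_iri",
    "looks_like_iri",
    "looks_like_curie",
]

TERM_TABLE_COLUMNS = (
    "curie",
    "iri",
    "label",
    "source",
    "obsolete",
    "linked_organism_curie",
)

_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*:\S+$")


class TermTableError(ValueError):
    """A term table file violates the dialect (duplicate IRI, bad CURIE...)."""


class NotFound:
    """Marker returned when a query matches no term."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NOT_FOUND"

    def __bool__(self) -> bool:
        return False


NOT_FOUND = NotFound()


@dataclass(frozen=True)
class Ambiguity:
    """A label query matched terms from more than one entry."""

    query: str
    candidates: tuple[OntologyTerm, ...]

    def __bool__(self) -> bool:
        return False


def looks_like_iri(value: str) -> bool:
    return "://" in value or value.startswith("urn:")


def looks_like_curie(value: str) -> bool:
    return not looks_like_iri(value) and bool(_CURIE_RE.match(value))


def expand_curie(curie: str, prefix_map: dict[str, str]) -> Optional[str]:
    """Absolute IRI for a CURIE, or None when the prefix is unmapped."""
    prefix, _, local = curie.partition(":")
    ns = prefix_map.get(prefix)
    return None if ns is None else ns + local


def compact_iri(iri: str, prefix_map: dict[str, str]) -> str:
    """CURIE form of an IRI under the longest matching namespace, else
    the IRI unchanged."""
    best = None
    for prefix, ns in prefix_map.items():
        if iri.startswith(ns) and (best is None or len(ns) > len(best[1])):
            best = (prefix, ns)
    if best is None:
        return iri
    prefix, ns = best
    return f"{prefix}:{iri[len(ns):]}"


@dataclass
class TermTable:
    """Ontology terms keyed by IRI, with the CURIE prefix map in force."""

    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    prefix_map: dict[str, str] = field(default_factory=default_prefix_map)
    version_label: str = ""

    def __post_init__(self) -> None:
        self._by_curie = {t.curie: t for t in self.terms.values()}
        self._by_label: dict[str, list[OntologyTerm]] = {}
        for t in sorted(self.terms.values(), key=lambda t: t.iri):
            self._by_label.setdefault(t.label.casefold(), []).append(t)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, iri: str) -> bool:
        return iri in self.terms

    def get(self, iri: str) -> Optional[OntologyTerm]:
        return self.terms.get(iri)


def _parse_bool(value: str, context: str) -> bool:
    if value == "true":
        return True
    if value == "false":
        return False
    raise TermTableError(f"{context}: obsolete must be 'true' or 'false', got {value!r}")


def _table_from_rows(
    rows: Iterable[dict[str, Optional[str]]],
    prefix_map: dict[str, str],
    version_label: str,
    origin: str,
) -> TermTable:
    terms: dict[str, OntologyTerm] = {}
    for lineno, row in enumerate(rows, start=2):
        curie = (row.get("curie") or "").strip()
        iri = (row.get("iri") or "").strip()
        label = (row.get("label") or "").strip()
        source = (row.get("source") or "").strip()
        obsolete = _parse_bool(
            (row.get("obsolete") or "false").strip(), f"{origin}:{lineno}"
        )
        linked = (row.get("linked_organism_curie") or "").strip()
        if iri in terms:
            raise TermTableError(
                f"{origin}:{lineno}: duplicate IRI {iri} "
                f"(already defined as {terms[iri].curie} {terms[iri].label!r})"
            )
        expected = expand_curie(curie, prefix_map)
        if expected is not None and expected != iri:
            raise TermTableError(
                f"{origin}:{lineno}: CURIE {curie} expands to {expected}, "
                f"not the stored IRI {iri}"
            )
        linked_iri = None
        if linked:
            linked_iri = expand_curie(linked, prefix_map) or linked
        terms[iri] = OntologyTerm(
            iri=iri,
            curie=curie,
            label=label,
            source=source,
            obsolete=obsolete,
            linked_organism_iri=linked_iri,
        )
    return TermTable(terms=terms, prefix_map=prefix_map, version_label=version_label)


def load_term_table(
    path: str,
    prefix_map: Optional[dict[str, str]] = None,
    version_label: str = "",
) -> TermTable:
    """Load a term table TSV, rejecting duplicate IRIs and CURIEs that
    do not expand to their stored IRI under the prefix map."""
    if prefix_map is None:
        prefix_map = default_prefix_map()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = tuple(reader.fieldnames or ())
        if header != TERM_TABLE_COLUMNS:
            raise TermTableError(
                f"{path}: expected header {list(TERM_TABLE_COLUMNS)}, got {list(header)}"
            )
        return _table_from_rows(reader, prefix_map, version_label, path)


def default_term_table() -> TermTable:
    """The packaged mini term table used by the worked examples and
    fixtures."""
    text = resources.files("immune_exposure.data").joinpath("terms.tsv").read_text(
        encoding="utf-8"
    )
    import io as _io

    reader = csv.DictReader(_io.StringIO(text), delimiter="\t")
    return _table_from_rows(
        reader, default_prefix_map(), "packaged", "terms.tsv"
    )


def resolve(
    query: str, table: TermTable
) -> Union[OntologyTerm, NotFound, Ambiguity]:
    """Resolve a label, CURIE or IRI to a term.

    IRI and CURIE queries match exactly (an exact IRI match always wins);
    label queries match case-insensitively. A label shared by several
    terms returns an :class:`Ambiguity` listing the candidates; no match
    returns :data:`NOT_FOUND`. Both markers are falsy.
    """
    query = query.strip()
    if looks_like_iri(query):
        return table.terms.get(query, NOT_FOUND)
    if looks_like_curie(query):
        term = table._by_curie.get(query)
        if term is not None:
            return term
        iri = expand_curie(query, table.prefix_map)
        if iri is not None and iri in table.terms:
            return table.terms[iri]
        return NOT_FOUND
    candidates = table._by_label.get(query.casefold(), [])
    if not candidates:
        return NOT_FOUND
    if len(candidates) > 1:
        return Ambiguity(query=query, candidates=tuple(candidates))
    return candidates[0]


@dataclass(frozen=True)
class TermDiff:
    """Set-semantic difference of two table versions, by IRI."""

    added: frozenset[str]
    removed: frozenset[str]
    relabeled: frozenset[tuple[str, str, str]]
    newly_obsolete: frozenset[str]

    def is_empty(self) -> bool:
        return not (
            self.added or self.removed or self.relabeled or self.newly_obsolete
        )


def diff_term_tables(old: TermTable, new: TermTable) -> TermDiff:
    """What changed between two versions of a term table.

    ``relabeled`` covers IRIs present in both with unequal labels;
    ``newly_obsolete`` covers IRIs obsolete in ``new`` but not ``old``.
    An IRI both relabeled and newly obsoleted is reported only as newly
    obsolete, keeping the four sets pairwise disjoint.
    """
    old_iris = set(old.terms)
    new_iris = set(new.terms)
    newly_obsolete = frozenset(
        iri
        for iri in old_iris & new_iris
        if new.terms[iri].obsolete and not old.terms[iri].obsolete
    )
    relabeled = frozenset(
        (iri, old.terms[iri].label, new.terms[iri].label)
        for iri in old_iris & new_iris
        if old.terms[iri].label != new.terms[iri].label
        and iri not in newly_obsolete
    )
    return TermDiff(
        added=frozenset(new_iris - old_iris),
        removed=frozenset(old_iris - new_iris),
        relabeled=relabeled,
        newly_obsolete=newly_obsolete,
    )


def _term_reference_fields(record: ExposureRecord) -> list[tuple[str, str]]:
    """(field, value) pairs of the record's ontology-term references.

    Material and disease are always term references; the stage is one
    only when written as a CURIE or IRI (controlled stage *labels* are
    checked against the stage vocabulary instead, rule IE07).
    """
    refs = []
    for fld in ("material", "disease"):
        value = getattr(record, fld)
        if not is_absent(value):
            refs.append((fld, value))
    if not is_absent(record.stage) and (
        looks_like_iri(record.stage) or looks_like_curie(record.stage)
    ):
        refs.append(("stage", record.stage))
    return refs


def check_record_terms(
    records: Iterable[ExposureRecord],
    table: TermTable,
    config: Optional[RuleConfig] = None,
) -> list[Finding]:
    """IE08 (unknown term) and IE09 (obsolete term) findings for every
    term reference in the given records."""
    if config is None:
        config = RuleConfig.default()
    findings = []
    for record in records:
        per_record = []
        for fld, value in _term_reference_fields(record):
            result = resolve(value, table)
            if result is NOT_FOUND:
                per_record.append(
                    Finding(
                        rule_id="IE08",
                        field=fld,
                        record_id=record.record_id,
                        severity=config.severity("IE08"),
                        message=f"{fld} reference {value!r} not found in term table",
                    )
                )
            elif isinstance(result, OntologyTerm) and result.obsolete:
                per_record.append(
                    Finding(
                        rule_id="IE09",
                        field=fld,
                        record_id=record.record_id,
                        severity=config.severity("IE09"),
                        message=(
                            f"{fld} reference {value!r} resolves to obsolete "
                            f"term {result.curie} ({result.label})"
                        ),
                    )
                )
        findings.extend(sorted(per_record, key=lambda f: (f.rule_id, f.field)))
    return findings
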