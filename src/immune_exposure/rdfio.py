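"""Record batch I/O (TSV, JSON Lines) and canonical RDF export.

Records travel between resources as flat tables; for cross-resource
querying they are triplified into an RDF graph, one subject per record,
with one predicate per model aspect plus the source resource. N-Triples
is the canonical serialization because its line-per-triple form can be
sorted into byte-reproducible output.

The demonstration query — all records whose hosts were exposed to a
given organism, regardless of disease state and optionally including
vaccinated subjects whose vaccine derives from that organism — is
implemented directly over record lists (:func:`query_by_material`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional
from urllib.parse import quote, unquote

from rdflib import Graph, Literal, URIRef

from .model import ExposureRecord, default_prefix_map, is_absent
from .terms import (
    TermTable,
    compact_iri,
    expand_curie,
    looks_like_curie,
    looks_like_iri,
    resolve,
)
from .model import OntologyTerm

__all__ = [
    "TSV_HEADER",
    "VOCAB_NS",
    "DEFAULT_BASE_IRI",
    "ParseError",
    "ExportError",
    "TripleSet",
    "read_records",
    "write_records",
    "export_ntriples",
    "import_ntriples",
    "query_by_material",
]

TSV_HEADER = (
    "record_id",
    "source_resource",
    "exposure_process",
    "exposure_material",
    "disease_name",
    "disease_stage",
    "free_text_original",
)

#: Predicate namespace of this package's triplification.
VOCAB_NS = "https://w3id.org/immune-exposure/vocab#"
DEFAULT_BASE_IRI = "https://w3id.org/immune-exposure/record/"

_PREDICATES = {
    "process": URIRef(VOCAB_NS + "hasExposureProcess"),
    "material": URIRef(VOCAB_NS + "hasExposureMaterial"),
    "disease": URIRef(VOCAB_NS + "hasDiseaseName"),
    "stage": URIRef(VOCAB_NS + "hasDiseaseStage"),
    "source": URIRef(VOCAB_NS + "sourceResource"),
}
_FIELD_BY_PREDICATE = {
    str(_PREDICATES["process"]): "process",
    str(_PREDICATES["material"]): "material",
    str(_PREDICATES["disease"]): "disease",
    str(_PREDICATES["stage"]): "stage",
    str(_PREDICATES["source"]): "source_resource",
}


class ParseError(ValueError):
    """A record file violates its dialect; carries the offending line."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ExportError(ValueError):
    """A record cannot be triplified (e.g. unexpandable CURIE)."""


def _record_from_row(row: dict[str, str], line: int) -> ExposureRecord:
    def clean(key: str) -> Optional[str]:
        value = (row.get(key) or "").strip()
        return value or None

    record_id = (row.get("record_id") or "").strip()
    if not record_id:
        raise ParseError("missing record_id", line)
    return ExposureRecord(
        record_id=record_id,
        source_resource=(row.get("source_resource") or "").strip(),
        process=clean("exposure_process"),
        material=clean("exposure_material"),
        disease=clean("disease_name"),
        stage=clean("disease_stage"),
        free_text_original=clean("free_text_original"),
    )


def _row_from_record(record: ExposureRecord) -> dict[str, str]:
    return {
        "record_id": record.record_id,
        "source_resource": record.source_resource or "",
        "exposure_process": record.process or "",
        "exposure_material": record.material or "",
        "disease_name": record.disease or "",
        "disease_stage": record.stage or "",
        "free_text_original": record.free_text_original or "",
    }


def _check_unique_ids(records: list[ExposureRecord]) -> None:
    seen: dict[str, int] = {}
    for i, r in enumerate(records, start=2):
        if r.record_id in seen:
            raise ParseError(
                f"duplicate record_id {r.record_id!r} "
                f"(first seen on line {seen[r.record_id]})",
                i,
            )
        seen[r.record_id] = i


def read_records(path: str, dialect: Optional[str] = None) -> list[ExposureRecord]:
    """Read a record batch from TSV or JSONL (dialect inferred from the
    file extension when not given)."""
    if dialect is None:
        dialect = "jsonl" if str(path).endswith((".jsonl", ".json")) else "tsv"
    dialect = dialect.lower()
    records: list[ExposureRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        if dialect == "tsv":
            header_line = fh.readline().rstrip("\n")
            header = tuple(header_line.split("\t"))
            if header != TSV_HEADER:
                raise ParseError(
                    f"expected header {list(TSV_HEADER)}, got {list(header)}", 1
                )
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                cells = line.split("\t")
                if len(cells) != len(TSV_HEADER):
                    raise ParseError(
                        f"expected {len(TSV_HEADER)} columns, got {len(cells)}",
                        lineno,
                    )
                records.append(
                    _record_from_row(dict(zip(TSV_HEADER, cells)), lineno)
                )
        elif dialect == "jsonl":
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"invalid JSON: {exc}", lineno) from exc
                if not isinstance(obj, dict):
                    raise ParseError("each line must be a JSON object", lineno)
                unknown = set(obj) - set(TSV_HEADER)
                if unknown:
                    raise ParseError(
                        f"unknown keys {sorted(unknown)}", lineno
                    )
                records.append(_record_from_row(obj, lineno))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    _check_unique_ids(records)
    return records


def write_records(
    records: Iterable[ExposureRecord], path: str, dialect: Optional[str] = None
) -> None:
    """Write a record batch as TSV or JSONL; empty cells denote absence."""
    if dialect is None:
        dialect = "jsonl" if str(path).endswith((".jsonl", ".json")) else "tsv"
    dialect = dialect.lower()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if dialect == "tsv":
            fh.write("\t".join(TSV_HEADER) + "\n")
            for r in records:
                row = _row_from_record(r)
                fh.write("\t".join(row[k] for k in TSV_HEADER) + "\n")
        elif dialect == "jsonl":
            for r in records:
                fh.write(
                    json.dumps(_row_from_record(r), ensure_ascii=False) + "\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


@dataclass(frozen=True)
class TripleSet:
    """An exported graph with its byte-reproducible serialization."""

    triples: frozenset[tuple]
    base_iri: str

    def serialize(self) -> str:
        """Sorted, newline-terminated N-Triples text."""
        lines = sorted(
            (s.n3(), p.n3(), o.n3()) for (s, p, o) in self.triples
        )
        return "".join(f"{s} {p} {o} .\n" for s, p, o in lines)

    def __len__(self) -> int:
        return len(self.triples)


def _object_node(value: str, prefix_map: dict[str, str], record_id: str):
    if looks_like_iri(value):
        return URIRef(value)
    if looks_like_curie(value):
        prefix = value.partition(":")[0]
        if prefix in prefix_map:
            return URIRef(expand_curie(value, prefix_map))
        if prefix.isupper() or prefix == "NCBITaxon":
            raise ExportError(
                f"record {record_id!r}: cannot expand CURIE {value!r} "
                f"(prefix {prefix!r} not in prefix map)"
            )
    return Literal(value)


def export_ntriples(
    records: Iterable[ExposureRecord],
    base_iri: str = DEFAULT_BASE_IRI,
    prefix_map: Optional[dict[str, str]] = None,
) -> tuple[TripleSet, str]:
    """Triplify records: subject ``<base_iri + percent-encoded id>``,
    one triple per present aspect plus sourceResource.

    Term references written as CURIEs are expanded to absolute IRIs via
    the prefix map; plain labels become literals. Returns the triple set
    and its canonical serialization.
    """
    if prefix_map is None:
        prefix_map = default_prefix_map()
    triples = set()
    for r in records:
        subject = URIRef(base_iri + quote(r.record_id, safe=""))
        triples.add((subject, _PREDICATES["source"], Literal(r.source_resource or "")))
        for fld in ("process", "material", "disease", "stage"):
            value = getattr(r, fld)
            if is_absent(value):
                continue
            if fld == "process":
                node = Literal(value)
            else:
                node = _object_node(value, prefix_map, r.record_id)
            triples.add((subject, _PREDICATES[fld], node))
    tset = TripleSet(triples=frozenset(triples), base_iri=base_iri)
    return tset, tset.serialize()


def import_ntriples(
    text: str,
    base_iri: str = DEFAULT_BASE_IRI,
    prefix_map: Optional[dict[str, str]] = None,
) -> tuple[list[ExposureRecord], list[str]]:
    """Parse N-Triples produced by :func:`export_ntriples` back into
    records.

    IRIs compact back to CURIEs under the prefix map where possible.
    Triples with predicates outside the package namespace are skipped and
    reported in the returned warning list. Records come back sorted by
    record_id.
    """
    if prefix_map is None:
        prefix_map = default_prefix_map()
    graph = Graph()
    if text.strip():
        graph.parse(data=text, format="nt")
    by_id: dict[str, ExposureRecord] = {}
    warnings: list[str] = []
    for s, p, o in graph:
        pred = str(p)
        fld = _FIELD_BY_PREDICATE.get(pred)
        if fld is None:
            warnings.append(f"ignored triple with foreign predicate {pred}")
            continue
        subject = str(s)
        if not subject.startswith(base_iri):
            warnings.append(
                f"ignored subject outside base IRI {base_iri}: {subject}"
            )
            continue
        record_id = unquote(subject[len(base_iri):])
        record = by_id.setdefault(record_id, ExposureRecord(record_id=record_id))
        if isinstance(o, URIRef):
            value = compact_iri(str(o), prefix_map)
        else:
            value = str(o)
        if fld == "source_resource":
            record.source_resource = value
        else:
            setattr(record, fld, value or None)
    records = [by_id[k] for k in sorted(by_id)]
    return records, sorted(warnings)


def query_by_material(
    records: Iterable[ExposureRecord],
    target_organism: str,
    include_vaccines: bool = False,
    term_table: Optional[TermTable] = None,
) -> list[str]:
    """Record ids of exposures to a given organism, across all process
    types and regardless of disease state.

    ``target_organism`` is an IRI (a CURIE is accepted and expanded). A
    record matches when its material resolves to that organism; with
    ``include_vaccines`` it also matches when the material is a product
    term (e.g. a vaccine) whose ``linked_organism_iri`` is the target, so
    vaccinated subjects that were never infected are retrieved too.
    """
    if term_table is None:
        from .terms import default_term_table

        term_table = default_term_table()
    target_iri = target_organism
    if looks_like_curie(target_organism):
        expanded = expand_curie(target_organism, term_table.prefix_map)
        if expanded is not None:
            target_iri = expanded
    matches = set()
    for r in records:
        if is_absent(r.material):
            continue
        material_iri = None
        resolved = resolve(r.material, term_table)
        if isinstance(resolved, OntologyTerm):
            material_iri = resolved.iri
            if include_vaccines and resolved.linked_organism_iri == target_iri:
                matches.add(r.record_id)
        elif looks_like_iri(r.material):
            material_iri = r.material
        elif looks_like_curie(r.material):
            material_iri = expand_curie(r.material, term_table.prefix_map)
        if material_iri == target_iri:
            matches.add(r.record_id)
    return sorted(matches)
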