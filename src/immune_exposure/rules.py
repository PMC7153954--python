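"""Rule catalogue and finding types for record validation.

Each validation rule has a stable code (IE01..IE09) and a default
severity. Cross-field structural rules (unknown process, required field
missing, forbidden field present, disease/stage pairing) default to
ERROR; ontology-binding hygiene rules (incompatible material source,
uncontrolled stage label, unknown or obsolete term) default to WARNING
and can be promoted via configuration.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

__all__ = [
    "ERROR",
    "WARNING",
    "Finding",
    "RuleConfig",
    "rule_catalogue",
]

ERROR = "ERROR"
WARNING = "WARNING"

FIELDS = ("process", "material", "disease", "stage", "cross-field")


def rule_catalogue() -> dict[str, tuple[str, str]]:
    """rule_id -> (default_severity, description), from the packaged TSV."""
    text = resources.files("immune_exposure.data").joinpath("rules.tsv").read_text(
        encoding="utf-8"
    )
    out = {}
    for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
        out[row["rule_id"]] = (row["default_severity"], row["description"])
    return out


@dataclass(frozen=True, order=True)
class Finding:
    """A rule-coded validation outcome attached to one record field."""

    rule_id: str
    field: str
    record_id: str
    severity: str
    message: str

    def __post_init__(self) -> None:
        if not self.message:
            raise ValueError("Finding.message must be nonempty")
        if self.field not in FIELDS:
            raise ValueError(f"unknown finding field {self.field!r}")


@dataclass(frozen=True)
class RuleConfig:
    """Severity assignment per rule, overridable and strict-promotable."""

    severities: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "RuleConfig":
        return cls(
            severities={
                rule: sev for rule, (sev, _) in rule_catalogue().items()
            }
        )

    @classmethod
    def from_overrides(cls, path: Optional[str] = None) -> "RuleConfig":
        """Default severities with per-rule overrides from a two-column
        TSV (rule_id, severity)."""
        severities = dict(cls.default().severities)
        if path is not None:
            with open(path, encoding="utf-8", newline="") as fh:
                for row in csv.reader(fh, delimiter="\t"):
                    if not row or row[0].startswith("#") or row[0] == "rule_id":
                        continue
                    rule_id, severity = row[0].strip(), row[1].strip().upper()
                    if severity not in (ERROR, WARNING):
                        raise ValueError(
                            f"invalid severity {severity!r} for {rule_id}"
                        )
                    severities[rule_id] = severity
        return cls(severities=severities)

    def strict(self) -> "RuleConfig":
        """Promote every WARNING to ERROR."""
        return RuleConfig(severities={r: ERROR for r in self.severities})

    def severity(self, rule_id: str) -> str:
        return self.severities.get(rule_id, ERROR)
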