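"""Machine-readable interaction rulebank.

A rule encodes one potential drug-drug interaction (PDDI) class screened by a
retrospective drug-utilization-review program: two disjoint sets of interacting
generic drugs (object drug vs precipitant), a severity flag, the management
strategies offered to the prescriber, and — for rules that can be evaluated
from claims — a map from each interacting drug to the therapeutic alternatives
whose initiation counts as a successful change.

The built-in bank ships 18 rules, 13 of them evaluable; the remaining 5 are
education-only (their recommended management leaves no signature in dispensing
claims).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger(__name__)

BUILTIN_RULEBANK = "builtin"
_BUILTIN_RESOURCE = "rulebank.yaml"


class RulebankError(ValueError):
    """Raised when a rule file violates the documented schema or invariants."""


class Severity(str, Enum):
    MAJOR = "major"
    MODERATE = "moderate"
    MINOR = "minor"


class StrategyKind(str, Enum):
    """The five management options offered in a prescriber alert."""

    CONTINUE_EDUCATE = "continue_educate"
    MODIFY_DOSE = "modify_dose"
    MONITOR = "monitor"
    CHANGE_ALTERNATIVE = "change_alternative"
    HOLD_DISCONTINUE = "hold_discontinue"


@dataclass(frozen=True)
class DrugConcept:
    """A generic-ingredient-level drug with claims-convention attributes."""

    drug_id: str
    generic_name: str
    class_tags: frozenset[str]
    maintenance: bool

    def __post_init__(self) -> None:
        if not self.drug_id or not self.generic_name:
            raise RulebankError("drug_id and generic_name must be non-empty")


@dataclass(frozen=True)
class ManagementStrategy:
    kind: StrategyKind
    text: str


@dataclass(frozen=True)
class InteractionRule:
    """One PDDI class: interacting drug sets plus recommended management.

    ``alternatives`` is keyed by the interacting drug actually dispensed, so a
    partner-conditional recommendation applies only when that drug was involved
    in the detected episode.
    """

    rule_id: str
    display_name: str
    set_a: frozenset[str]
    set_b: frozenset[str]
    severity: Severity
    evaluable: bool
    strategies: tuple[ManagementStrategy, ...]
    alternatives: Mapping[str, frozenset[str]]
    plan_exclusions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.set_a or not self.set_b:
            raise RulebankError(f"rule {self.rule_id!r}: both drug sets must be non-empty")
        if self.set_a & self.set_b:
            raise RulebankError(
                f"rule {self.rule_id!r}: set_a and set_b overlap: {sorted(self.set_a & self.set_b)}"
            )
        if self.evaluable and not self.alternatives:
            raise RulebankError(
                f"rule {self.rule_id!r}: evaluable rules must list therapeutic alternatives"
            )
        members = self.set_a | self.set_b
        for drug, alts in self.alternatives.items():
            if drug not in members:
                raise RulebankError(
                    f"rule {self.rule_id!r}: alternatives keyed by {drug!r}, "
                    "which is not an interacting drug of this rule"
                )
            bad = alts & members
            if bad:
                raise RulebankError(
                    f"rule {self.rule_id!r}: recommended alternatives {sorted(bad)} are "
                    "themselves interacting drugs of the rule"
                )

    @property
    def members(self) -> frozenset[str]:
        return self.set_a | self.set_b

    def alternatives_for(self, involved: Iterable[str]) -> frozenset[str]:
        """Alternatives recommended for an episode involving the given drugs."""
        out: set[str] = set()
        for drug in involved:
            out |= self.alternatives.get(drug, frozenset())
        return frozenset(out)


# ---------------------------------------------------------------------------
# loading / serialization


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise RulebankError(f"{context}: missing required field {key!r}")
    return mapping[key]


def _parse_drug(raw: Mapping) -> DrugConcept:
    ctx = f"drug {raw.get('drug_id', '<missing id>')!r}"
    return DrugConcept(
        drug_id=str(_require(raw, "drug_id", ctx)),
        generic_name=str(_require(raw, "generic_name", ctx)),
        class_tags=frozenset(_require(raw, "class_tags", ctx)),
        maintenance=bool(_require(raw, "maintenance", ctx)),
    )


def _parse_rule(raw: Mapping) -> InteractionRule:
    ctx = f"rule {raw.get('rule_id', '<missing id>')!r}"
    try:
        severity = Severity(_require(raw, "severity", ctx))
    except ValueError as exc:
        raise RulebankError(f"{ctx}: invalid severity {raw['severity']!r}") from exc
    strategies = []
    for s in _require(raw, "strategies", ctx):
        try:
            kind = StrategyKind(_require(s, "kind", ctx))
        except ValueError as exc:
            raise RulebankError(f"{ctx}: invalid strategy kind {s.get('kind')!r}") from exc
        strategies.append(ManagementStrategy(kind=kind, text=str(_require(s, "text", ctx))))
    alternatives = {
        str(drug): frozenset(str(a) for a in alts)
        for drug, alts in (raw.get("alternatives") or {}).items()
    }
    return InteractionRule(
        rule_id=str(_require(raw, "rule_id", ctx)),
        display_name=str(_require(raw, "display_name", ctx)),
        set_a=frozenset(str(d) for d in _require(raw, "set_a", ctx)),
        set_b=frozenset(str(d) for d in _require(raw, "set_b", ctx)),
        severity=severity,
        evaluable=bool(_require(raw, "evaluable", ctx)),
        strategies=tuple(strategies),
        alternatives=alternatives,
        plan_exclusions=frozenset(str(p) for p in raw.get("plan_exclusions") or ()),
    )


def load_rulebank(path_or_builtin: str | Path = BUILTIN_RULEBANK) -> list[InteractionRule]:
    """Load and validate a rulebank from YAML/JSON, or the shipped built-in.

    The file holds one document with a ``rules`` key (list of rule objects) and
    optionally a ``drugs`` key (the drug dictionary; see :func:`load_drug_dictionary`).
    Rules are returned sorted by ``rule_id``. An empty file yields an empty list
    with a warning.
    """
    doc = _read_rulebank_document(path_or_builtin)
    if not doc or not doc.get("rules"):
        logger.warning("rulebank %s contains no rules", path_or_builtin)
        return []
    rules = [_parse_rule(raw) for raw in doc["rules"]]
    seen: set[str] = set()
    for rule in rules:
        if rule.rule_id in seen:
            raise RulebankError(f"duplicate rule_id {rule.rule_id!r}")
        seen.add(rule.rule_id)
    return sorted(rules, key=lambda r: r.rule_id)


def load_drug_dictionary(path_or_builtin: str | Path = BUILTIN_RULEBANK) -> dict[str, DrugConcept]:
    """Load the drug dictionary shipped alongside a rulebank."""
    doc = _read_rulebank_document(path_or_builtin)
    drugs = [_parse_drug(raw) for raw in (doc.get("drugs") or [])]
    out: dict[str, DrugConcept] = {}
    for drug in drugs:
        if drug.drug_id in out:
            raise RulebankError(f"duplicate drug_id {drug.drug_id!r}")
        out[drug.drug_id] = drug
    return out


def _read_rulebank_document(path_or_builtin: str | Path) -> dict:
    if path_or_builtin == BUILTIN_RULEBANK:
        text = resources.files("ddialert.data").joinpath(_BUILTIN_RESOURCE).read_text()
    else:
        text = Path(path_or_builtin).read_text()
    try:
        doc = yaml.safe_load(text)  # JSON is a YAML subset, so both parse here
    except yaml.YAMLError as exc:
        raise RulebankError(f"cannot parse rulebank {path_or_builtin}: {exc}") from exc
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise RulebankError("rulebank document must be a mapping with a 'rules' key")
    return doc


def serialize_rulebank(rules: Iterable[InteractionRule], path: str | Path) -> None:
    """Write rules back to YAML; round-trips field-for-field through load."""
    payload = {
        "rules": [
            {
                "rule_id": r.rule_id,
                "display_name": r.display_name,
                "set_a": sorted(r.set_a),
                "set_b": sorted(r.set_b),
                "severity": r.severity.value,
                "evaluable": r.evaluable,
                "plan_exclusions": sorted(r.plan_exclusions),
                "strategies": [{"kind": s.kind.value, "text": s.text} for s in r.strategies],
                "alternatives": {d: sorted(a) for d, a in sorted(r.alternatives.items())},
            }
            for r in sorted(rules, key=lambda r: r.rule_id)
        ]
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def drugs_in_scope(rules: Iterable[InteractionRule]) -> frozenset[str]:
    """Union of all interacting and alternative drug ids across rules.

    Superset of every drug id the detection engine may match or the outcome
    stage may look for.
    """
    out: set[str] = set()
    for rule in rules:
        out |= rule.set_a | rule.set_b
        for alts in rule.alternatives.values():
            out |= alts
    return frozenset(out)
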