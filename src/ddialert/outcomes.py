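"""Successful-change outcome ascertainment.

A "successful change" is the initiation — a non-reversed fill — of a
therapeutic alternative recommended for the drugs actually involved in the
episode, within 90 days after the index date. The window is half-open on the
left: day 0 (the index fill itself) is excluded, day 90 is included. Both arms
are ascertained against their own index dates. Success does not require the
interacting drugs to stop; an optional strict-switch mode additionally demands
that neither interacting drug is refilled in the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Iterable, Sequence

import pandas as pd

from .claims_model import Claim
from .detection import PddiEvent
from .matching import MatchedPair
from .rulebase import InteractionRule


class AscertainmentError(ValueError):
    """Outcome requested for a rule with no recommended alternatives."""


@dataclass(frozen=True)
class OutcomeRecord:
    event_id: str
    rule_id: str
    patient_id: str
    arm: str  # "intervention" | "control"
    success: bool
    change_drug_id: str | None = None
    days_to_change: int | None = None

    def __post_init__(self) -> None:
        present = (self.change_drug_id is not None, self.days_to_change is not None)
        if self.success != all(present) or (not self.success and any(present)):
            raise ValueError("success flag and change fields must be jointly present/absent")


def _ascertain_event(
    event: PddiEvent,
    arm: str,
    claims: Sequence[Claim],
    rule: InteractionRule,
    window_days: int,
    strict_switch: bool,
    incident_alternative: bool,
    index_offset_days: int,
) -> OutcomeRecord:
    if not rule.alternatives:
        raise AscertainmentError(
            f"rule {rule.rule_id!r} has no recommended alternatives (education-only?)"
        )
    involved = event.involved_drugs
    alt_set = rule.alternatives_for(involved) - involved
    index = event.index_date + timedelta(days=index_offset_days)
    win_end = index + timedelta(days=window_days)

    if incident_alternative:
        lookback_start = index - timedelta(days=180)
        prior = {
            c.drug_id for c in claims
            if not c.reversed and lookback_start <= c.fill_date <= index
        }
        alt_set = alt_set - prior

    hit: Claim | None = None
    for c in claims:
        if c.reversed or c.drug_id not in alt_set:
            continue
        if index < c.fill_date <= win_end:
            if hit is None or (c.fill_date, c.claim_id) < (hit.fill_date, hit.claim_id):
                hit = c

    if hit is not None and strict_switch:
        refilled = any(
            not c.reversed and c.drug_id in involved and index < c.fill_date <= win_end
            for c in claims
        )
        if refilled:
            hit = None

    if hit is None:
        return OutcomeRecord(event.event_id, event.rule_id, event.patient_id, arm, False)
    return OutcomeRecord(
        event.event_id, event.rule_id, event.patient_id, arm, True,
        change_drug_id=hit.drug_id,
        days_to_change=(hit.fill_date - index).days,
    )


def ascertain(
    pairs: Iterable[MatchedPair],
    intervention_claims: dict[str, list[Claim]],
    control_claims: dict[str, list[Claim]],
    rules: Sequence[InteractionRule],
    window_days: int = 90,
    strict_switch: bool = False,
    incident_alternative: bool = False,
    index_offset_days: int = 0,
) -> list[OutcomeRecord]:
    """Ascertain the binary outcome for both arms of every matched pair.

    ``*_claims`` map patient id to that patient's full claims history.
    ``index_offset_days`` shifts the window start relative to the index fill
    (e.g. 1 to count from the next-morning alert rather than the fill itself).
    """
    by_rule = {r.rule_id: r for r in rules}
    records: list[OutcomeRecord] = []
    for pair in pairs:
        rule = by_rule[pair.rule_id]
        records.append(_ascertain_event(
            pair.intervention_event, "intervention",
            intervention_claims.get(pair.intervention_event.patient_id, ()),
            rule, window_days, strict_switch, incident_alternative, index_offset_days))
        records.append(_ascertain_event(
            pair.control_event, "control",
            control_claims.get(pair.control_event.patient_id, ()),
            rule, window_days, strict_switch, incident_alternative, index_offset_days))
    return records


def change_breakdown(
    records: Iterable[OutcomeRecord],
    rules: Sequence[InteractionRule] | None = None,
) -> pd.DataFrame:
    """Counts of alternative drugs chosen, per rule; sums match success counts."""
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        if rec.success:
            key = (rec.rule_id, rec.change_drug_id)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"rule_id": rid, "change_drug_id": drug, "n": n}
        for (rid, drug), n in sorted(counts.items(), key=lambda kv: (kv[0][0], -kv[1], kv[0][1]))
    ]
    return pd.DataFrame(rows, columns=["rule_id", "change_drug_id", "n"])


def records_frame(records: Iterable[OutcomeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"event_id": r.event_id, "rule_id": r.rule_id, "patient_id": r.patient_id,
             "arm": r.arm, "success": r.success, "change_drug_id": r.change_drug_id or "",
             "days_to_change": "" if r.days_to_change is None else r.days_to_change}
            for r in records
        ],
        columns=["event_id", "rule_id", "patient_id", "arm", "success",
                 "change_drug_id", "days_to_change"],
    )
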