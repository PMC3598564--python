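"""Co-exposure detection and alert attribution.

Emulates a PBM's nightly claims scan as an equivalent batch sweep: for each
patient and interaction rule, overlapping active-supply windows of a drug from
each of the rule's two sets define a co-exposure episode. A new episode begins
only after co-exposure has lapsed for more than ``grace`` days. Each episode
yields exactly one event, indexed at the fill date of the second interacting
claim, and the alert is addressed to that claim's prescriber.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import date, timedelta
from typing import Iterable, Sequence

from .claims_model import Claim, ClaimsData, active_supply_window
from .rulebase import InteractionRule

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PddiEvent:
    """One detected co-exposure episode for one patient and rule."""

    event_id: str
    rule_id: str
    patient_id: str
    first_claim: Claim
    second_claim: Claim
    index_date: date
    alert_prescriber: str
    alerted: bool = False
    evaluable: bool = True

    @property
    def involved_drugs(self) -> frozenset[str]:
        return frozenset({self.first_claim.drug_id, self.second_claim.drug_id})


def _order_pair(ca: Claim, cb: Claim) -> tuple[Claim, Claim]:
    """Chronological (first, second); same-day fills put the set_b claim second."""
    if ca.fill_date < cb.fill_date:
        return ca, cb
    if cb.fill_date < ca.fill_date:
        return cb, ca
    return ca, cb  # ca from set_a, cb from set_b by construction


def _merge_intervals(
    intervals: list[tuple[date, date]], grace: int
) -> list[tuple[date, date]]:
    """Merge half-open intervals, joining gaps of at most ``grace`` days."""
    merged: list[tuple[date, date]] = []
    gap = timedelta(days=grace)
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def detect_events(
    data: ClaimsData,
    rules: Sequence[InteractionRule],
    scan_window: tuple[date, date] | None = None,
    grace: int = 0,
    incident_only: bool = False,
) -> list[PddiEvent]:
    """Find every maximal co-exposure episode as one event.

    Reversed claims are excluded. When ``scan_window`` (half-open) is given,
    only events whose index date lies inside it are returned. With
    ``incident_only``, only the earliest episode per (patient, rule) is kept,
    approximating a program that alerts on incident co-exposure only.
    Events are ordered by (index_date, patient_id, rule_id).
    """
    by_patient = data.claims_by_patient()
    events: list[PddiEvent] = []
    for rule in rules:
        for patient_id, claims in by_patient.items():
            a_claims = [c for c in claims if c.drug_id in rule.set_a]
            b_claims = [c for c in claims if c.drug_id in rule.set_b]
            if not a_claims or not b_claims:
                continue
            events.extend(_episodes_for(rule, patient_id, a_claims, b_claims, grace,
                                        incident_only))
    if scan_window is not None:
        lo, hi = scan_window
        events = [e for e in events if lo <= e.index_date < hi]
    events.sort(key=lambda e: (e.index_date, e.patient_id, e.rule_id))
    return [
        replace(e, event_id=f"E{i:07d}") for i, e in enumerate(events, start=1)
    ]


def _episodes_for(
    rule: InteractionRule,
    patient_id: str,
    a_claims: list[Claim],
    b_claims: list[Claim],
    grace: int,
    incident_only: bool,
) -> list[PddiEvent]:
    # overlap intervals of all (set_a, set_b) claim pairs, tagged by their pair
    pair_overlaps: list[tuple[date, date, Claim, Claim]] = []
    for ca in a_claims:
        sa, ea = active_supply_window(ca)
        for cb in b_claims:
            sb, eb = active_supply_window(cb)
            start, end = max(sa, sb), min(ea, eb)
            if start < end:
                pair_overlaps.append((start, end, ca, cb))
    if not pair_overlaps:
        return []
    episodes = _merge_intervals([(s, e) for s, e, _, _ in pair_overlaps], grace)
    out: list[PddiEvent] = []
    for ep_start, ep_end in episodes:
        members = [(s, e, ca, cb) for s, e, ca, cb in pair_overlaps
                   if s < ep_end and e > ep_start]
        # the triggering pair: earliest moment both drugs were on hand,
        # ties broken toward the set_b claim then lexicographic claim ids
        def trigger_key(item: tuple[date, date, Claim, Claim]):
            _, _, ca, cb = item
            first, second = _order_pair(ca, cb)
            return (max(ca.fill_date, cb.fill_date), second.claim_id, first.claim_id)

        _, _, ca, cb = min(members, key=trigger_key)
        first, second = _order_pair(ca, cb)
        out.append(PddiEvent(
            event_id="",  # assigned after the global sort
            rule_id=rule.rule_id,
            patient_id=patient_id,
            first_claim=first,
            second_claim=second,
            index_date=second.fill_date,
            alert_prescriber=second.prescriber_id,
            evaluable=rule.evaluable,
        ))
        if incident_only:
            break
    return out


def build_alerts(
    events: Iterable[PddiEvent],
    rules: Sequence[InteractionRule],
    patients=None,
) -> list[PddiEvent]:
    """Mark which detected events generate a prescriber alert.

    One alert per (patient, rule, episode) — the detection stage's episode
    deduplication already guarantees this, so re-scanning the same episode can
    never re-alert. A rule excluded for a patient's plan (line of business)
    is suppressed; education-only rules still alert but stay non-evaluable.
    """
    by_rule = {r.rule_id: r for r in rules}
    out: list[PddiEvent] = []
    for event in events:
        rule = by_rule[event.rule_id]
        lob = event.second_claim.lob
        suppressed = lob in rule.plan_exclusions
        out.append(replace(event, alerted=not suppressed, evaluable=rule.evaluable))
    n_alerts = sum(e.alerted for e in out)
    logger.info("build_alerts: %d events in, %d alerts generated", len(out), n_alerts)
    return out


def eligibility_filter(
    events: Iterable[PddiEvent],
    patients: dict,
    horizon_days: int = 90,
) -> list[PddiEvent]:
    """Keep events whose patient stays plan-eligible for the follow-up horizon.

    An event survives iff ``eligibility_end >= index_date + horizon_days``.
    """
    events = list(events)
    kept = [
        e for e in events
        if patients[e.patient_id].eligibility_end >= e.index_date + timedelta(days=horizon_days)
    ]
    logger.info("eligibility_filter: %d events in, %d with >= %d days of follow-up",
                len(events), len(kept), horizon_days)
    return kept


def alert_counts(events: Iterable[PddiEvent]) -> dict[str, int]:
    """Alerts sent per rule (alerted events only)."""
    counts: dict[str, int] = {}
    for e in events:
        if e.alerted:
            counts[e.rule_id] = counts.get(e.rule_id, 0) + 1
    return counts
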