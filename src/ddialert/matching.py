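"""1:1 matched-control construction.

Each alerted (intervention) event is matched to at most one control event from
the non-alerted pool on the same rule, gender, line of business, and detection
time period, with an age gap of at most ±2 years at the index date. A control
patient can enter only a single rule cohort across the whole study, even when
exposed to several interaction classes; intervention patients may appear in
several cohorts.

The matcher is greedy nearest-age-first: rules are processed in descending
intervention-event count, intervention events in patient-id order, and each is
paired with the unused candidate minimizing the absolute age gap (ties to the
lexicographically smallest control patient id). This is deterministic and
auditable; a maximum bipartite matching could pair marginally more events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date

import pandas as pd

from .claims_model import Patient, age_at
from .detection import PddiEvent

logger = logging.getLogger(__name__)

PERIOD_GRANULARITIES = ("month", "quarter")


@dataclass(frozen=True)
class MatchedPair:
    pair_id: str
    rule_id: str
    intervention_event: PddiEvent
    control_event: PddiEvent
    age_gap: int  # intervention minus control, completed years at index


def period_key(index_date: date, granularity: str = "month"):
    """Bucket an index date into the configured matching time period."""
    if granularity == "month":
        return (index_date.year, index_date.month)
    if granularity == "quarter":
        return (index_date.year, (index_date.month - 1) // 3)
    raise ValueError(f"unknown period granularity {granularity!r}")


def match_cohorts(
    intervention_events: list[PddiEvent],
    control_events: list[PddiEvent],
    intervention_patients: dict[str, Patient],
    control_patients: dict[str, Patient],
    period: str = "month",
    max_age_gap: int = 2,
    seed: int | None = None,
) -> tuple[list[MatchedPair], list[PddiEvent]]:
    """Greedy 1:1 matching under the cohort constraints.

    Returns the matched pairs and the unmatched intervention events. ``seed``
    is accepted for interface stability; the documented sort keys make the
    procedure fully deterministic, so it is unused.
    """
    if not control_events:
        logger.warning("match_cohorts: empty control pool; all %d events unmatched",
                       len(intervention_events))
        return [], list(intervention_events)

    # index the control pool by exact-match stratum
    pool: dict[tuple, list[tuple[int, PddiEvent]]] = {}
    for ev in control_events:
        pat = control_patients[ev.patient_id]
        key = (ev.rule_id, pat.gender, pat.lob, period_key(ev.index_date, period))
        pool.setdefault(key, []).append((age_at(pat, ev.index_date), ev))
    for bucket in pool.values():
        bucket.sort(key=lambda item: (item[1].patient_id, item[1].event_id))

    rule_order: dict[str, int] = {}
    for ev in intervention_events:
        rule_order[ev.rule_id] = rule_order.get(ev.rule_id, 0) + 1
    ordered = sorted(
        intervention_events,
        key=lambda e: (-rule_order[e.rule_id], e.rule_id, e.patient_id, e.event_id),
    )

    used_control_events: set[str] = set()
    used_control_patients: set[str] = set()  # one cohort per control patient, globally
    pairs: list[MatchedPair] = []
    unmatched: list[PddiEvent] = []
    for ev in ordered:
        pat = intervention_patients[ev.patient_id]
        case_age = age_at(pat, ev.index_date)
        key = (ev.rule_id, pat.gender, pat.lob, period_key(ev.index_date, period))
        best = None
        for ctl_age, ctl in pool.get(key, ()):
            if ctl.event_id in used_control_events or ctl.patient_id in used_control_patients:
                continue
            gap = case_age - ctl_age
            if abs(gap) > max_age_gap:
                continue
            cand = (abs(gap), ctl.patient_id, ctl, gap)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None:
            unmatched.append(ev)
            continue
        _, _, ctl, gap = best
        used_control_events.add(ctl.event_id)
        used_control_patients.add(ctl.patient_id)
        pairs.append(MatchedPair(
            pair_id=f"P{len(pairs) + 1:06d}",
            rule_id=ev.rule_id,
            intervention_event=ev,
            control_event=ctl,
            age_gap=gap,
        ))
    logger.info("match_cohorts: %d of %d intervention events matched",
                len(pairs), len(intervention_events))
    return pairs, unmatched


def cohort_summary(pairs: list[MatchedPair]) -> pd.DataFrame:
    """Per-rule matched-pair counts with percentage of total, plus a Total row."""
    counts: dict[str, int] = {}
    for p in pairs:
        counts[p.rule_id] = counts.get(p.rule_id, 0) + 1
    total = sum(counts.values())
    rows = [
        {"rule_id": rid, "n_pairs": n, "pct_of_total": 100.0 * n / total if total else 0.0}
        for rid, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    rows.append({"rule_id": "Total", "n_pairs": total,
                 "pct_of_total": 100.0 if total else 0.0})
    return pd.DataFrame(rows, columns=["rule_id", "n_pairs", "pct_of_total"])
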