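"""End-to-end orchestration: simulate -> detect -> match -> ascertain -> analyze.

Every run leaves a manifest (config hash, seed, package version, and the
stage-by-stage attrition chain: claims read, events detected, alerts sent,
alerts with follow-up eligibility, evaluable alerts, matched pairs, successes
per arm) so a run is auditable and bit-reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .claims_model import ClaimsData, age_at, read_claims
from .detection import PddiEvent, alert_counts, build_alerts, detect_events, eligibility_filter
from .matching import MatchedPair, cohort_summary, match_cohorts
from .outcomes import ascertain, change_breakdown, records_frame
from .rulebase import InteractionRule, load_drug_dictionary, load_rulebank
from .stats import (age_group, assign_rxrisk, fit_outcome_model, load_rxrisk_map,
                    pair_results_table, StatsError)
from .synthetic_data import SimConfig, SimulatedStudy, simulate_population, write_study

logger = logging.getLogger(__name__)


class DataError(ValueError):
    pass


@dataclass
class RunConfig:
    """Run configuration; flag defaults follow the study's definitions."""

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    intervention_dir: str | None = None  # used when simulate is False
    control_dir: str | None = None
    rulebank: str = "builtin"
    period: str = "month"
    outcome_window_days: int = 90
    eligibility_horizon_days: int = 90
    grace_days: int = 0
    incident_only: bool = False
    strict_switch: bool = False
    incident_alternative: bool = False
    sim: dict = field(default_factory=dict)  # SimConfig field overrides

    def __post_init__(self) -> None:
        if self.outcome_window_days <= 0 or self.eligibility_horizon_days <= 0:
            raise DataError("window lengths must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise DataError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**doc)

    def sim_config(self) -> SimConfig:
        overrides = dict(self.sim)
        for key in ("study_start", "study_end"):
            if key in overrides and isinstance(overrides[key], str):
                overrides[key] = date.fromisoformat(overrides[key])
        if "age_mix" in overrides:
            overrides["age_mix"] = tuple(overrides["age_mix"])
        return SimConfig(seed=self.seed, **overrides)


# ---------------------------------------------------------------------------
# covariate assembly


def build_covariate_frame(
    pairs: list[MatchedPair],
    outcome_records,
    intervention: ClaimsData,
    control: ClaimsData,
    rules: list[InteractionRule],
    rxrisk_map: dict | None = None,
    lookback_days: int = 180,
) -> pd.DataFrame:
    """One row per matched event with outcome and adjustment covariates."""
    if rxrisk_map is None:
        rxrisk_map = load_rxrisk_map()
    dictionary = load_drug_dictionary()
    by_rule = {r.rule_id: r for r in rules}
    success = {(r.event_id, r.arm): r.success for r in outcome_records}
    claims_i = intervention.claims_by_patient()
    claims_c = control.claims_by_patient()

    rows = []
    for pair in pairs:
        rule = by_rule[pair.rule_id]
        for arm, event, data, claims in (
            ("intervention", pair.intervention_event, intervention, claims_i),
            ("control", pair.control_event, control, claims_c),
        ):
            patient = data.patients[event.patient_id]
            prescriber = data.prescribers[event.alert_prescriber]
            acute = any(
                not dictionary[d].maintenance
                for d in event.involved_drugs if d in dictionary
            )
            flags = assign_rxrisk(claims.get(event.patient_id, ()), rxrisk_map,
                                  event.index_date, lookback_days)
            row = {
                "event_id": event.event_id,
                "rule_id": pair.rule_id,
                "success": success[(event.event_id, arm)],
                "intervention": arm == "intervention",
                "specialist": not prescriber.primary_care,
                "practitioner_type": prescriber.practitioner_type,
                "acute_medication": acute,
                "severity": rule.severity.value,
                "male": patient.gender == "M",
                "age_group": age_group(age_at(patient, event.index_date)),
            }
            row.update({f"rxrisk_{cat}": v for cat, v in flags.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def demographics_summary(
    events: list[PddiEvent], data: ClaimsData
) -> pd.DataFrame:
    """Age/gender/line-of-business breakdown of alerted patients, aggregated
    and per plan, in the style of a cohort demographics table."""
    rows = []
    for e in events:
        p = data.patients[e.patient_id]
        a = age_at(p, e.index_date)
        stratum = "<18" if a < 18 else "18-39" if a < 40 else "40-64" if a < 65 else ">=65"
        rows.append({"age_stratum": stratum, "gender": p.gender, "lob": p.lob})
    df = pd.DataFrame(rows, columns=["age_stratum", "gender", "lob"])
    out = []
    n_total = len(df)
    scopes = [("aggregated", df)] + [
        (lob, df[df["lob"] == lob]) for lob in ("commercial", "medicaid")
    ]
    for dim, levels in (("age_stratum", ["<18", "18-39", "40-64", ">=65"]),
                        ("gender", ["F", "M"]),
                        ("lob", ["commercial", "medicaid"])):
        for level in levels:
            entry = {"dimension": dim, "level": level}
            for scope_name, scope in scopes:
                n = int((scope[dim] == level).sum())
                entry[f"n_{scope_name}"] = n
                entry[f"pct_{scope_name}"] = 100.0 * n / len(scope) if len(scope) else 0.0
            out.append(entry)
    entry = {"dimension": "total", "level": "alerts"}
    for scope_name, scope in scopes:
        entry[f"n_{scope_name}"] = len(scope)
        entry[f"pct_{scope_name}"] = 100.0 if n_total else 0.0
    out.append(entry)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: RunConfig) -> Path:
    """Run the full study pipeline; returns the run directory.

    Stages: simulate (or load) claims; detect co-exposure events in both
    streams; build alerts (intervention stream only); filter on follow-up
    eligibility; match 1:1; ascertain 90-day outcomes; per-rule and pooled
    comparison; adjusted logistic model. Idempotent for a fixed seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rules = load_rulebank(config.rulebank)
    manifest: dict = {
        "config": _jsonable(asdict(config)),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    stages = manifest["stages"]

    if config.simulate:
        study = simulate_population(config.sim_config(), rules)
        write_study(study, out / "data")
        intervention, control = study.intervention, study.control
    else:
        if not config.intervention_dir or not config.control_dir:
            raise DataError("simulate=false requires intervention_dir and control_dir")
        intervention = read_claims(config.intervention_dir)
        control = read_claims(config.control_dir)
    stages["claims_read"] = {
        "intervention": len(intervention.claims), "control": len(control.claims)}

    scan = None
    events_i = detect_events(intervention, rules, scan_window=scan,
                             grace=config.grace_days, incident_only=config.incident_only)
    events_c = detect_events(control, rules, scan_window=scan,
                             grace=config.grace_days, incident_only=config.incident_only)
    stages["events_detected"] = {"intervention": len(events_i), "control": len(events_c)}

    alerts = [e for e in build_alerts(events_i, rules) if e.alerted]
    stages["alerts_sent"] = len(alerts)
    _events_frame(alerts).to_csv(out / "events.csv", index=False)

    eligible = eligibility_filter(alerts, intervention.patients,
                                  config.eligibility_horizon_days)
    stages["alerts_eligible"] = len(eligible)
    evaluable = [e for e in eligible if e.evaluable]
    stages["alerts_evaluable_eligible"] = len(evaluable)

    controls_eligible = eligibility_filter(
        [e for e in events_c if e.evaluable], control.patients,
        config.eligibility_horizon_days)
    _events_frame(controls_eligible).to_csv(out / "control_events.csv", index=False)

    pairs, unmatched = match_cohorts(
        evaluable, controls_eligible, intervention.patients, control.patients,
        period=config.period, seed=config.seed)
    stages["matched_pairs"] = len(pairs)
    stages["unmatched_interventions"] = len(unmatched)
    _pairs_frame(pairs).to_csv(out / "pairs.csv", index=False)
    cohort_summary(pairs).to_csv(out / "cohort_summary.csv", index=False)

    records = ascertain(
        pairs, intervention.claims_by_patient(), control.claims_by_patient(), rules,
        window_days=config.outcome_window_days, strict_switch=config.strict_switch,
        incident_alternative=config.incident_alternative)
    records_frame(records).to_csv(out / "outcomes.csv", index=False)
    stages["successes"] = {
        "intervention": sum(r.success for r in records if r.arm == "intervention"),
        "control": sum(r.success for r in records if r.arm == "control"),
    }

    results = pair_results_table(records)
    results.to_csv(out / "pair_results.csv", index=False)
    change_breakdown(records).to_csv(out / "change_breakdown.csv", index=False)
    demographics_summary(eligible, intervention).to_csv(
        out / "demographics.csv", index=False)

    covariates = build_covariate_frame(pairs, records, intervention, control, rules)
    try:
        regression = fit_outcome_model(covariates)
        regression.to_frame().to_csv(out / "regression.csv", index=False)
        stages["regression"] = {"converged": True, "n_obs": regression.n_obs}
    except StatsError as exc:
        logger.warning("adjusted model not fitted: %s", exc)
        stages["regression"] = {"converged": False, "error": str(exc)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("attrition: %s", stages)
    return out


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(_jsonable(asdict(config)), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, date):
        return obj.isoformat()
    return obj


def _events_frame(events: list[PddiEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"event_id": e.event_id, "rule_id": e.rule_id, "patient_id": e.patient_id,
             "first_claim_id": e.first_claim.claim_id,
             "second_claim_id": e.second_claim.claim_id,
             "index_date": e.index_date.isoformat(),
             "alert_prescriber": e.alert_prescriber, "alerted": e.alerted}
            for e in events
        ],
        columns=["event_id", "rule_id", "patient_id", "first_claim_id",
                 "second_claim_id", "index_date", "alert_prescriber", "alerted"],
    )


def _pairs_frame(pairs: list[MatchedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"pair_id": p.pair_id, "rule_id": p.rule_id,
             "intervention_event_id": p.intervention_event.event_id,
             "intervention_patient_id": p.intervention_event.patient_id,
             "control_event_id": p.control_event.event_id,
             "control_patient_id": p.control_event.patient_id,
             "age_gap": p.age_gap}
            for p in pairs
        ],
        columns=["pair_id", "rule_id", "intervention_event_id", "intervention_patient_id",
                 "control_event_id", "control_patient_id", "age_gap"],
    )


# ---------------------------------------------------------------------------
# report rendering


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    cols = list(df.columns)
    def fmt(v):
        if isinstance(v, float):
            return floatfmt.format(v)
        return str(v)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    return "\n".join(lines)


def render_report(results_dir: str | Path) -> str:
    """Render the run's result tables as a markdown report.

    Every number is read from the results CSVs; nothing is recomputed here.
    """
    results_dir = Path(results_dir)
    required = results_dir / "pair_results.csv"
    if not required.exists():
        raise DataError(f"missing analysis outputs in {results_dir}")
    parts = ["# DUR alert evaluation report", ""]

    pair_results = pd.read_csv(required)
    if pair_results.empty:
        return "\n".join(parts + ["No events detected; nothing to report.", ""])

    demo = results_dir / "demographics.csv"
    if demo.exists():
        parts += ["## Alerted-patient demographics", "",
                  _md_table(pd.read_csv(demo), "{:.1f}"), ""]

    parts += ["## Successful changes by interaction class", "",
              _md_table(pair_results), "",
              "Test choice: Fisher exact when the minimum expected cell count is <= 5, "
              "otherwise uncorrected Pearson chi-square (1 df).", ""]

    reg = results_dir / "regression.csv"
    if reg.exists():
        parts += ["## Adjusted logistic model", "", _md_table(pd.read_csv(reg)), "",
                  "Reference levels: physician, moderate severity, age 65-79.", ""]

    manifest = results_dir / "manifest.json"
    if manifest.exists():
        stages = json.loads(manifest.read_text())["stages"]
        parts += ["## Attrition", "", "```", json.dumps(stages, indent=2, sort_keys=True),
                  "```", ""]
    report = "\n".join(parts)
    (results_dir / "report.md").write_text(report)
    return report
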