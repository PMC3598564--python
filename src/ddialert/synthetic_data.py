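"""Synthetic pharmacy-claims generator.

Generates two claims populations with the statistical structure the analysis
assumes — an intervention stream (plans where prescriber alerts are active) and
a control-pool stream drawn from separate plans — so every downstream stage can
be exercised and parameter recovery verified without real dispensing data.

What it emulates: a large commercial plan plus a small managed-Medicaid plan;
an elderly-skewed age mix; per-rule co-prescription frequencies proportional to
the observed alert volumes; per-rule baseline probabilities of initiating a
recommended alternative within 90 days; and a multiplicative intervention
effect on the odds of change for alerted episodes. Alongside the claims it
records a ground-truth table (latent change probability, assigned arm, planted
change) that the pipeline never reads — only tests do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .claims_model import Claim, ClaimsData, Patient, Prescriber, write_claims
from .rulebase import (InteractionRule, drugs_in_scope, load_drug_dictionary,
                       load_rulebank)
from .stats import load_rxrisk_map


class ConfigError(ValueError):
    pass


#: Relative co-prescription volume per evaluable rule (observed alert counts).
RULE_ALERT_WEIGHTS: dict[str, int] = {
    "warfarin_statins": 939,
    "warfarin_fibrates": 303,
    "statins_azoles": 247,
    "simvastatin_amiodarone": 169,
    "statins_macrolides": 140,
    "benzodiazepines_azoles": 86,
    "warfarin_azoles": 62,
    "ciprofloxacin_tizanidine": 24,
    "isotretinoin_tetracyclines": 15,
    "theophylline_quinolones": 12,
    "amiodarone_macrolides": 11,
    "amiodarone_quinolones": 7,
    "carbamazepine_macrolides": 4,
}

#: Education-only alert volumes, on the same relative scale. The study does not
#: break these out per class; the split is a calibration choice sized so the
#: education:evaluable alert ratio matches the reported totals.
EDUCATION_ALERT_WEIGHTS: dict[str, int] = {
    "warfarin_amiodarone": 600,
    "warfarin_thyroid": 500,
    "nitrates_pde5_inhibitors": 200,
    "amiodarone_sotalol": 100,
    "ergotamines_triptans": 41,
}

#: Control-arm 90-day change rates used as default baseline probabilities.
BASELINE_CHANGE_PROBS: dict[str, float] = {
    "warfarin_statins": 0.011,
    "warfarin_fibrates": 0.158,
    "statins_azoles": 0.008,
    "simvastatin_amiodarone": 0.018,
    "statins_macrolides": 0.300,
    "benzodiazepines_azoles": 0.047,
    "warfarin_azoles": 0.016,
    "ciprofloxacin_tizanidine": 0.458,
    "isotretinoin_tetracyclines": 0.067,
    "theophylline_quinolones": 0.167,
    "amiodarone_macrolides": 0.364,
    "amiodarone_quinolones": 0.286,
    "carbamazepine_macrolides": 0.500,
}

AGE_STRATA = ((2, 17), (18, 39), (40, 64), (65, 89))
SPECIALIST_SPECIALTIES = (
    "cardiology", "dermatology", "endocrinology", "gastroenterology",
    "infectious disease", "neurology", "pulmonology", "psychiatry",
)
PRIMARY_CARE_CHOICES = ("internal medicine", "general practice", "family practice")

#: Drugs outside every rule, used for noise fills (comorbidity-mapped + inert).
_INERT_NOISE = ("omeprazole", "loratadine", "acetaminophen_hydrocodone")


def _noise_drugs(rules: list[InteractionRule]) -> tuple[str, ...]:
    # comorbidity-mapped and inert drugs, excluding anything a rule could
    # match or count as a therapy change (noise must not plant outcomes)
    in_scope = drugs_in_scope(rules)
    seen: list[str] = []
    for spec in load_rxrisk_map().values():
        for d in spec["drugs"]:
            if d not in seen and d not in in_scope:
                seen.append(d)
    return tuple(seen) + _INERT_NOISE


@dataclass
class SimConfig:
    """Study-condition knobs for the generator; defaults mirror the study."""

    seed: int = 0
    n_patients_commercial: int = 9000
    n_patients_medicaid: int = 1000
    study_start: date = date(2010, 5, 1)
    study_end: date = date(2010, 11, 1)
    co_rx_rates: dict[str, float] = field(default_factory=dict)
    baseline_change_probs: dict[str, float] = field(default_factory=dict)
    intervention_odds_ratio: float = 1.186
    age_mix: tuple[float, float, float, float] = (0.002, 0.019, 0.282, 0.697)
    female_frac: float = 0.537
    prescriber_mix: dict[str, float] = field(default_factory=lambda: {
        "physician": 0.872, "nurse_practitioner": 0.060,
        "physician_assistant": 0.045, "other": 0.023,
    })
    primary_care_frac: float = 0.466
    eligible_frac: float = 0.88  # fraction with >= 90 days of follow-up eligibility
    noise_rate: float = 5.0  # noise fills per patient-year
    control_pool_scale: float = 2.0
    suppress_medicaid_benzo_azole: bool = True

    def __post_init__(self) -> None:
        if not self.co_rx_rates:
            # roughly proportional to observed alert volumes, floored so the
            # rarest cohorts stay populated at the default population scale
            total = sum(RULE_ALERT_WEIGHTS.values())
            self.co_rx_rates = {
                rid: max(0.5 * w / total, 0.004)
                for rid, w in {**RULE_ALERT_WEIGHTS, **EDUCATION_ALERT_WEIGHTS}.items()
            }
        if not self.baseline_change_probs:
            self.baseline_change_probs = dict(BASELINE_CHANGE_PROBS)

    def validate(self) -> None:
        probs = [self.female_frac, self.primary_care_frac, self.eligible_frac,
                 *self.co_rx_rates.values(), *self.baseline_change_probs.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if self.intervention_odds_ratio <= 0:
            raise ConfigError("intervention_odds_ratio must be positive")
        if not math.isclose(sum(self.age_mix), 1.0, abs_tol=1e-9):
            raise ConfigError("age_mix weights must sum to 1")
        if not math.isclose(sum(self.prescriber_mix.values()), 1.0, abs_tol=1e-9):
            raise ConfigError("prescriber_mix weights must sum to 1")
        if self.study_start >= self.study_end:
            raise ConfigError("study_start must precede study_end")
        if (self.n_patients_commercial + self.n_patients_medicaid) == 0 and any(
            r > 0 for r in self.co_rx_rates.values()
        ):
            raise ConfigError("positive co-prescription rates require patients")


def default_study_config(seed: int = 0) -> SimConfig:
    """The default configuration: demographics, plan split, and per-rule
    co-prescription volumes proportional to the observed study."""
    return SimConfig(seed=seed)


@dataclass
class SimulatedStudy:
    intervention: ClaimsData
    control: ClaimsData
    ground_truth: pd.DataFrame


def change_probability(baseline: float, odds_ratio: float, alerted: bool) -> float:
    """P(successful change) = expit(logit(baseline) + 1{alerted} * ln(OR))."""
    logit = math.log(baseline / (1.0 - baseline))
    if alerted:
        logit += math.log(odds_ratio)
    return 1.0 / (1.0 + math.exp(-logit))


def _sample_age_years(rng: np.random.Generator, age_mix) -> int:
    stratum = rng.choice(len(AGE_STRATA), p=np.asarray(age_mix, dtype=float))
    lo, hi = AGE_STRATA[stratum]
    return int(rng.integers(lo, hi + 1))


def _generate_prescribers(rng: np.random.Generator, n: int, prefix: str,
                          config: SimConfig) -> dict[str, Prescriber]:
    types = list(config.prescriber_mix)
    weights = np.array([config.prescriber_mix[t] for t in types], dtype=float)
    out: dict[str, Prescriber] = {}
    for i in range(n):
        ptype = types[rng.choice(len(types), p=weights)]
        if rng.random() < config.primary_care_frac:
            specialty = PRIMARY_CARE_CHOICES[rng.integers(len(PRIMARY_CARE_CHOICES))]
        else:
            specialty = SPECIALIST_SPECIALTIES[rng.integers(len(SPECIALIST_SPECIALTIES))]
        pid = f"{prefix}R{i + 1:05d}"
        out[pid] = Prescriber(pid, ptype, specialty)
    return out


def _supply_days(rng: np.random.Generator, maintenance: bool) -> int:
    if maintenance:
        return int(rng.choice([30, 60, 90], p=[0.6, 0.2, 0.2]))
    return int(rng.integers(7, 15))


def _generate_arm(
    rng: np.random.Generator,
    config: SimConfig,
    rules: list[InteractionRule],
    maintenance_flags: dict[str, bool],
    noise_drugs: tuple[str, ...],
    arm: str,
) -> tuple[ClaimsData, list[dict]]:
    prefix = "I-" if arm == "intervention" else "C-"
    scale = 1.0 if arm == "intervention" else config.control_pool_scale
    n_comm = int(round(config.n_patients_commercial * scale))
    n_medi = int(round(config.n_patients_medicaid * scale))
    n_total = n_comm + n_medi
    prescribers = _generate_prescribers(
        rng, max(20, n_total // 25), prefix, config)
    prescriber_ids = sorted(prescribers)

    noise_start = config.study_start - timedelta(days=180)
    window_years = (config.study_end - noise_start).days / 365.25

    patients: dict[str, Patient] = {}
    claims: list[Claim] = []
    truth: list[dict] = []
    claim_seq = 0

    def new_claim(pid: str, drug: str, fill: date, supply: int, prescriber: str,
                  lob: str) -> Claim:
        nonlocal claim_seq
        claim_seq += 1
        c = Claim(f"{prefix}C{claim_seq:07d}", pid, drug, fill, supply, prescriber, lob)
        claims.append(c)
        return c

    for i in range(n_total):
        lob = "commercial" if i < n_comm else "medicaid"
        pid = f"{prefix}P{i + 1:06d}"
        age = _sample_age_years(rng, config.age_mix)
        birth = config.study_start - timedelta(
            days=int(age * 365.25) + int(rng.integers(0, 365)))
        gender = "F" if rng.random() < config.female_frac else "M"
        elig_start = config.study_start - timedelta(days=365)
        if rng.random() < config.eligible_frac:
            elig_end = config.study_end + timedelta(days=180)
        else:
            elig_end = config.study_start + timedelta(
                days=int(rng.integers(0, (config.study_end - config.study_start).days + 60)))
        patients[pid] = Patient(pid, birth, gender, lob, elig_start, elig_end)

        for rule in rules:
            rate = config.co_rx_rates.get(rule.rule_id, 0.0)
            if rate <= 0.0 or rng.random() >= rate:
                continue
            if (config.suppress_medicaid_benzo_azole and lob == "medicaid"
                    and "medicaid" in rule.plan_exclusions):
                continue
            drug_a = sorted(rule.set_a)[rng.integers(len(rule.set_a))]
            drug_b = sorted(rule.set_b)[rng.integers(len(rule.set_b))]
            span = (config.study_end - config.study_start).days - 14
            first_fill = config.study_start + timedelta(days=int(rng.integers(0, span)))
            supply_a = _supply_days(rng, maintenance_flags.get(drug_a, True))
            offset = int(rng.integers(0, min(supply_a, 21)))
            second_fill = first_fill + timedelta(days=offset)
            supply_b = _supply_days(rng, maintenance_flags.get(drug_b, True))
            pr_a, pr_b = rng.choice(len(prescriber_ids), size=2, replace=False)
            new_claim(pid, drug_a, first_fill, supply_a, prescriber_ids[pr_a], lob)
            second = new_claim(pid, drug_b, second_fill, supply_b, prescriber_ids[pr_b], lob)

            alerted = (arm == "intervention" and lob not in rule.plan_exclusions)
            if not rule.evaluable:
                continue
            baseline = config.baseline_change_probs.get(rule.rule_id, 0.0)
            p = change_probability(baseline, config.intervention_odds_ratio, alerted)
            changed = bool(rng.random() < p)
            change_drug = ""
            days_to_change = -1
            if changed:
                alts = sorted(rule.alternatives_for({drug_a, drug_b}))
                change_drug = alts[rng.integers(len(alts))]
                days_to_change = int(rng.integers(1, 91))
                new_claim(pid, change_drug, second_fill + timedelta(days=days_to_change),
                          30, second.prescriber_id, lob)
            truth.append({
                "population": arm, "patient_id": pid, "rule_id": rule.rule_id,
                "index_date": second_fill.isoformat(), "alerted": alerted,
                "p_change": p, "changed": changed, "change_drug_id": change_drug,
                "days_to_change": days_to_change,
            })

        n_noise = rng.poisson(config.noise_rate * window_years)
        for _ in range(n_noise):
            drug = noise_drugs[rng.integers(len(noise_drugs))]
            fill = noise_start + timedelta(
                days=int(rng.integers(0, (config.study_end - noise_start).days)))
            new_claim(pid, drug, fill, 30,
                      prescriber_ids[rng.integers(len(prescriber_ids))], lob)

    return ClaimsData(patients, prescribers, claims), truth


def simulate_population(
    config: SimConfig,
    rules: list[InteractionRule] | None = None,
) -> SimulatedStudy:
    """Generate intervention and control-pool populations plus ground truth.

    Fully deterministic for a fixed ``config.seed``.
    """
    config.validate()
    if rules is None:
        rules = load_rulebank()
    dictionary = load_drug_dictionary()
    maintenance_flags = {d.drug_id: d.maintenance for d in dictionary.values()}
    noise = _noise_drugs(rules)
    rng = np.random.default_rng(config.seed)
    intervention, truth_i = _generate_arm(rng, config, rules, maintenance_flags,
                                          noise, "intervention")
    control, truth_c = _generate_arm(rng, config, rules, maintenance_flags,
                                     noise, "control")
    truth = pd.DataFrame(
        truth_i + truth_c,
        columns=["population", "patient_id", "rule_id", "index_date", "alerted",
                 "p_change", "changed", "change_drug_id", "days_to_change"],
    )
    return SimulatedStudy(intervention, control, truth)


def write_study(study: SimulatedStudy, directory: str | Path) -> None:
    """Write intervention/ and control/ claim tables plus ground_truth.csv."""
    directory = Path(directory)
    write_claims(study.intervention, directory / "intervention")
    write_claims(study.control, directory / "control")
    study.ground_truth.to_csv(directory / "ground_truth.csv", index=False)
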