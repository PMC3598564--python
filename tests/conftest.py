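from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from ddialert.claims_model import Claim, ClaimsData, Patient, Prescriber
from ddialert.rulebase import load_rulebank
from ddialert.synthetic_data import SimConfig, simulate_population


@pytest.fixture(scope="session")
def rules():
    return load_rulebank()


@pytest.fixture(scope="session")
def rules_by_id(rules):
    return {r.rule_id: r for r in rules}


def make_patient(pid="P1", birth=date(1945, 6, 1), gender="F", lob="commercial",
                 elig_start=date(2009, 1, 1), elig_end=date(2011, 12, 31)) -> Patient:
    return Patient(pid, birth, gender, lob, elig_start, elig_end)


def make_prescriber(prid="R1", ptype="physician", specialty="cardiology") -> Prescriber:
    return Prescriber(prid, ptype, specialty)


_claim_seq = [0]


def make_claim(patient="P1", drug="warfarin", fill=date(2010, 5, 1), supply=30,
               prescriber="R1", lob="commercial", reversed_=False, claim_id=None) -> Claim:
    _claim_seq[0] += 1
    return Claim(claim_id or f"C{_claim_seq[0]:05d}", patient, drug, fill, supply,
                 prescriber, lob, reversed_)


def make_data(patients, prescribers, claims) -> ClaimsData:
    return ClaimsData({p.patient_id: p for p in patients},
                      {r.prescriber_id: r for r in prescribers},
                      list(claims))


def random_population(rng: np.random.Generator, rules, n_patients=40, n_claims=200,
                      lob_mix=(0.9, 0.1)):
    """Random claims touching rule drugs, for oracle-equivalence checks."""
    drug_pool = sorted({d for r in rules for d in (r.set_a | r.set_b)})
    patients = [
        make_patient(
            pid=f"P{i}",
            birth=date(1990, 1, 1) - timedelta(days=int(rng.integers(0, 365 * 60))),
            gender="F" if rng.random() < 0.5 else "M",
            lob="commercial" if rng.random() < lob_mix[0] else "medicaid",
        )
        for i in range(n_patients)
    ]
    prescribers = [make_prescriber(f"R{i}") for i in range(8)]
    claims = []
    for j in range(n_claims):
        pat = patients[rng.integers(n_patients)]
        claims.append(Claim(
            f"C{j:05d}", pat.patient_id,
            drug_pool[rng.integers(len(drug_pool))],
            date(2010, 5, 1) + timedelta(days=int(rng.integers(0, 170))),
            int(rng.integers(1, 91)),
            f"R{rng.integers(8)}", pat.lob,
            reversed=bool(rng.random() < 0.05),
        ))
    return make_data(patients, prescribers, claims)


@pytest.fixture(scope="session")
def small_study(rules):
    """A modest synthetic study reused by several suites."""
    cfg = SimConfig(seed=7, n_patients_commercial=1800, n_patients_medicaid=200,
                    control_pool_scale=2.0)
    return simulate_population(cfg, rules)
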