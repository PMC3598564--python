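"""Core data model and CSV I/O for patients, prescribers, and dispensing claims.

Conventions: all date intervals are half-open ``[start, end)`` at day
resolution; a claim's active-supply window runs from the fill date for
``days_supply`` days; reversed (voided) claims are carried in memory but
excluded from every downstream computation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta
from pathlib import Path

import pandas as pd

PATIENT_COLUMNS = ["patient_id", "birth_date", "gender", "lob", "eligibility_start", "eligibility_end"]
PRESCRIBER_COLUMNS = ["prescriber_id", "practitioner_type", "primary_specialty"]
CLAIM_COLUMNS = ["claim_id", "patient_id", "drug_id", "fill_date", "days_supply",
                 "prescriber_id", "lob", "reversed"]

GENDERS = ("F", "M")
LOBS = ("commercial", "medicaid")
PRACTITIONER_TYPES = ("physician", "nurse_practitioner", "physician_assistant", "other")

#: Primary specialties that define a primary-care practitioner.
PRIMARY_CARE_SPECIALTIES = frozenset({"internal medicine", "general practice", "family practice"})


class SchemaError(ValueError):
    """A table is missing required columns or has unparseable values."""


class IntegrityError(ValueError):
    """A claim references a patient or prescriber that does not exist."""


@dataclass(frozen=True)
class Patient:
    patient_id: str
    birth_date: date
    gender: str
    lob: str
    eligibility_start: date
    eligibility_end: date

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise SchemaError(f"patient {self.patient_id}: invalid gender {self.gender!r}")
        if self.lob not in LOBS:
            raise SchemaError(f"patient {self.patient_id}: invalid lob {self.lob!r}")
        if self.eligibility_start > self.eligibility_end:
            raise SchemaError(f"patient {self.patient_id}: eligibility interval inverted")


@dataclass(frozen=True)
class Prescriber:
    prescriber_id: str
    practitioner_type: str
    primary_specialty: str

    def __post_init__(self) -> None:
        if self.practitioner_type not in PRACTITIONER_TYPES:
            raise SchemaError(
                f"prescriber {self.prescriber_id}: invalid practitioner_type "
                f"{self.practitioner_type!r}"
            )

    @property
    def primary_care(self) -> bool:
        return self.primary_specialty in PRIMARY_CARE_SPECIALTIES


@dataclass(frozen=True)
class Claim:
    claim_id: str
    patient_id: str
    drug_id: str
    fill_date: date
    days_supply: int
    prescriber_id: str
    lob: str
    reversed: bool = False

    def __post_init__(self) -> None:
        if self.days_supply < 1:
            raise SchemaError(f"claim {self.claim_id}: days_supply must be >= 1")


@dataclass
class ClaimsData:
    """One population's tables, with lookups by id."""

    patients: dict[str, Patient]
    prescribers: dict[str, Prescriber]
    claims: list[Claim]

    def claims_by_patient(self, include_reversed: bool = False) -> dict[str, list[Claim]]:
        out: dict[str, list[Claim]] = {pid: [] for pid in self.patients}
        for claim in self.claims:
            if claim.reversed and not include_reversed:
                continue
            out.setdefault(claim.patient_id, []).append(claim)
        for lst in out.values():
            lst.sort(key=lambda c: (c.fill_date, c.claim_id))
        return out


def active_supply_window(claim: Claim) -> tuple[date, date]:
    """Half-open exposure interval ``[fill_date, fill_date + days_supply)``."""
    return claim.fill_date, claim.fill_date + timedelta(days=claim.days_supply)


def age_at(patient: Patient, index: date) -> int:
    """Completed years of age at the index date."""
    if index < patient.birth_date:
        raise ValueError(
            f"patient {patient.patient_id}: index {index} precedes birth {patient.birth_date}"
        )
    b = patient.birth_date
    return index.year - b.year - ((index.month, index.day) < (b.month, b.day))


# ---------------------------------------------------------------------------
# CSV I/O


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def _to_date(value: str, context: str) -> date:
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise SchemaError(f"{context}: invalid ISO date {value!r}") from exc


def read_claims(directory: str | Path) -> ClaimsData:
    """Read ``patients.csv``, ``prescribers.csv``, ``claims.csv`` from a directory.

    Enforces referential integrity: every claim must resolve to a known patient
    and prescriber. Reversed claims are retained but flagged.
    """
    directory = Path(directory)
    frames = {}
    for name, cols in (("patients", PATIENT_COLUMNS), ("prescribers", PRESCRIBER_COLUMNS),
                       ("claims", CLAIM_COLUMNS)):
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing table file {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        _check_columns(df, cols, name)
        frames[name] = df

    patients = {}
    for row in frames["patients"].itertuples(index=False):
        p = Patient(
            patient_id=row.patient_id,
            birth_date=_to_date(row.birth_date, f"patient {row.patient_id}"),
            gender=row.gender,
            lob=row.lob,
            eligibility_start=_to_date(row.eligibility_start, f"patient {row.patient_id}"),
            eligibility_end=_to_date(row.eligibility_end, f"patient {row.patient_id}"),
        )
        patients[p.patient_id] = p

    prescribers = {}
    for row in frames["prescribers"].itertuples(index=False):
        pr = Prescriber(row.prescriber_id, row.practitioner_type, row.primary_specialty)
        prescribers[pr.prescriber_id] = pr

    claims = []
    dangling: list[str] = []
    for row in frames["claims"].itertuples(index=False):
        if row.patient_id not in patients:
            dangling.append(f"claim {row.claim_id}: unknown patient {row.patient_id}")
            continue
        if row.prescriber_id not in prescribers:
            dangling.append(f"claim {row.claim_id}: unknown prescriber {row.prescriber_id}")
            continue
        claims.append(Claim(
            claim_id=row.claim_id,
            patient_id=row.patient_id,
            drug_id=row.drug_id,
            fill_date=_to_date(row.fill_date, f"claim {row.claim_id}"),
            days_supply=int(row.days_supply),
            prescriber_id=row.prescriber_id,
            lob=row.lob,
            reversed=str(row.reversed).strip().lower() in ("true", "1", "yes"),
        ))
    if dangling:
        raise IntegrityError("dangling foreign keys:\n" + "\n".join(dangling))
    return ClaimsData(patients=patients, prescribers=prescribers, claims=claims)


def write_claims(data: ClaimsData, directory: str | Path) -> None:
    """Write the three tables as CSV; inverse of :func:`read_claims`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            (p.patient_id, p.birth_date.isoformat(), p.gender, p.lob,
             p.eligibility_start.isoformat(), p.eligibility_end.isoformat())
            for p in data.patients.values()
        ],
        columns=PATIENT_COLUMNS,
    ).to_csv(directory / "patients.csv", index=False)
    pd.DataFrame(
        [(pr.prescriber_id, pr.practitioner_type, pr.primary_specialty)
         for pr in data.prescribers.values()],
        columns=PRESCRIBER_COLUMNS,
    ).to_csv(directory / "prescribers.csv", index=False)
    pd.DataFrame(
        [
            (c.claim_id, c.patient_id, c.drug_id, c.fill_date.isoformat(), c.days_supply,
             c.prescriber_id, c.lob, str(c.reversed).lower())
            for c in data.claims
        ],
        columns=CLAIM_COLUMNS,
    ).to_csv(directory / "claims.csv", index=False)


def drop_reversed(data: ClaimsData) -> ClaimsData:
    """A view of the data with reversed claims removed."""
    return replace(data, claims=[c for c in data.claims if not c.reversed])
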