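"""Two-arm inference and the covariate-adjusted outcome model.

Per interaction class, successful-change counts in the two matched arms form a
2x2 table. Test choice follows expected cell counts: a two-sided Fisher exact
test when the minimum expected count (row total x column total / N) is 5 or
less, otherwise an uncorrected Pearson chi-square with 1 df. The pooled
analysis collapses all matched events into a single 2x2 table; matched-pair
dependence is deliberately ignored in the primary analysis (a McNemar variant
is available as an extension).

The adjusted analysis is a maximum-likelihood logistic regression of success
on the intervention indicator plus prescriber, drug, and patient covariates,
with reference levels physician / moderate severity / age 65-79.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
import statsmodels.api as sm

from .claims_model import Claim
from .outcomes import OutcomeRecord

logger = logging.getLogger(__name__)

CHI_SQUARE = "chi_square"
FISHER_EXACT = "fisher_exact"

#: Expected-count threshold below or at which the exact test is used.
EXPECTED_COUNT_THRESHOLD = 5.0

AGE_GROUPS = ("0-49", "50-64", "65-79", "80+")
AGE_REFERENCE = "65-79"
SEVERITY_REFERENCE = "moderate"
PRACTITIONER_REFERENCE = "physician"


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PairResult:
    rule_id: str
    n_per_arm: int
    changes_intervention: int
    changes_control: int
    test_used: str
    p_value: float

    @property
    def rate_intervention(self) -> float:
        return self.changes_intervention / self.n_per_arm

    @property
    def rate_control(self) -> float:
        return self.changes_control / self.n_per_arm


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise StatsError(f"need a non-negative integer 2x2 table, got {table!r}")
    if t.sum() == 0:
        raise StatsError("all-zero table: association undefined")
    return t


def expected_counts(table) -> np.ndarray:
    """Expected cell counts under independence: row total x col total / N."""
    t = _as_table(table)
    n = t.sum()
    if n == 0:
        raise StatsError("all-zero table")
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / n


def choose_test(table) -> str:
    """Fisher exact iff the minimum expected cell count is <= 5, else chi-square.

    A zero row or column margin forces the exact test (the chi-square statistic
    is undefined there).
    """
    t = _as_table(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return FISHER_EXACT
    if expected_counts(t).min() <= EXPECTED_COUNT_THRESHOLD:
        return FISHER_EXACT
    return CHI_SQUARE


def fisher_two_sided(table) -> float:
    """Conventional two-sided Fisher exact p: the sum of hypergeometric
    outcomes with point probability at most that of the observed table."""
    _, p = sps.fisher_exact(_as_table(table), alternative="two-sided")
    return float(p)


def chi_square_uncorrected(table) -> float:
    """Uncorrected Pearson chi-square p-value with 1 df."""
    _, p, _, _ = sps.chi2_contingency(_as_table(table), correction=False)
    return float(p)


def compare_arms(table) -> tuple[str, float]:
    """Two-sided p-value for a 2x2 table under the documented test choice."""
    t = _as_table(table)
    test = choose_test(t)
    p = chi_square_uncorrected(t) if test == CHI_SQUARE else fisher_two_sided(t)
    return test, p


def mcnemar_pairs(n_discordant_10: int, n_discordant_01: int) -> float:
    """Exact McNemar p-value from discordant-pair counts (extension, off by default)."""
    res = sm.stats.contingency_tables.mcnemar(
        [[0, n_discordant_10], [n_discordant_01, 0]], exact=True
    )
    return float(res.pvalue)


def pair_result(rule_id: str, n_per_arm: int, changes_intervention: int,
                changes_control: int) -> PairResult:
    table = [
        [changes_intervention, n_per_arm - changes_intervention],
        [changes_control, n_per_arm - changes_control],
    ]
    test, p = compare_arms(table)
    return PairResult(rule_id, n_per_arm, changes_intervention, changes_control, test, p)


def pair_results_table(records: Iterable[OutcomeRecord]) -> pd.DataFrame:
    """Per-rule two-arm comparison plus a pooled Total row."""
    df = pd.DataFrame(
        [(r.rule_id, r.arm, int(r.success)) for r in records],
        columns=["rule_id", "arm", "success"],
    )
    if df.empty:
        return pd.DataFrame(columns=["rule_id", "n_per_arm", "changes_intervention",
                                     "rate_intervention", "changes_control",
                                     "rate_control", "test_used", "p_value"])
    rows = []
    groups = sorted(
        df.groupby("rule_id"),
        key=lambda kv: (-len(kv[1]), kv[0]),
    )
    pooled = [0, 0, 0]  # n per arm, intervention changes, control changes
    for rule_id, g in groups:
        n = int((g["arm"] == "intervention").sum())
        ci = int(g.loc[g["arm"] == "intervention", "success"].sum())
        cc = int(g.loc[g["arm"] == "control", "success"].sum())
        res = pair_result(rule_id, n, ci, cc)
        pooled[0] += n
        pooled[1] += ci
        pooled[2] += cc
        rows.append(res)
    rows.append(pair_result("Total", *pooled))
    return pd.DataFrame(
        [
            {"rule_id": r.rule_id, "n_per_arm": r.n_per_arm,
             "changes_intervention": r.changes_intervention,
             "rate_intervention": r.rate_intervention,
             "changes_control": r.changes_control,
             "rate_control": r.rate_control,
             "test_used": r.test_used, "p_value": r.p_value}
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# comorbidity proxy


def load_rxrisk_map(path: str | Path | None = None) -> dict[str, dict]:
    """Load the shipped (or a custom) medication-to-comorbidity lookup."""
    if path is None:
        text = resources.files("ddialert.data").joinpath("rxrisk.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return doc["categories"]


def assign_rxrisk(
    patient_claims: Sequence[Claim],
    category_map: Mapping[str, Mapping],
    index_date: date,
    lookback_days: int = 180,
) -> dict[str, bool]:
    """Flag each comorbidity category with >= 1 mapped claim in the lookback window.

    Unknown drugs are ignored. Flags are monotone in the claims set.
    """
    start = index_date - timedelta(days=lookback_days)
    drug_to_cats: dict[str, list[str]] = {}
    for cat, spec in category_map.items():
        for drug in spec["drugs"]:
            drug_to_cats.setdefault(drug, []).append(cat)
    flags = {cat: False for cat in category_map}
    for claim in patient_claims:
        if claim.reversed or not (start <= claim.fill_date <= index_date):
            continue
        for cat in drug_to_cats.get(claim.drug_id, ()):
            flags[cat] = True
    return flags


# ---------------------------------------------------------------------------
# adjusted logistic model


@dataclass(frozen=True)
class RegressionResult:
    terms: tuple[str, ...]
    coefficients: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    converged: bool
    n_obs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "coefficient": self.coefficients,
            "p_value": self.p_values,
            "odds_ratio": self.odds_ratios,
            "or_ci_lower": self.ci_lower,
            "or_ci_upper": self.ci_upper,
        })

    def term(self, name: str) -> dict[str, float]:
        i = self.terms.index(name)
        return {
            "coefficient": float(self.coefficients[i]),
            "p_value": float(self.p_values[i]),
            "odds_ratio": float(self.odds_ratios[i]),
            "or_ci_lower": float(self.ci_lower[i]),
            "or_ci_upper": float(self.ci_upper[i]),
        }


def age_group(age: int) -> str:
    if age <= 49:
        return "0-49"
    if age <= 64:
        return "50-64"
    if age <= 79:
        return "65-79"
    return "80+"


def build_design_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code the covariate table with the documented reference levels.

    Expected columns (all optional except ``intervention``): ``intervention``,
    ``specialist``, ``practitioner_type``, ``acute_medication``, ``severity``,
    ``male``, ``age_group``, and any number of ``rxrisk_*`` indicator columns.
    """
    X = pd.DataFrame(index=df.index)
    X["intervention"] = df["intervention"].astype(int)
    if "specialist" in df:
        X["specialist"] = df["specialist"].astype(int)
    if "practitioner_type" in df:
        for level in ("nurse_practitioner", "physician_assistant", "other"):
            if (df["practitioner_type"] == level).any():
                X[f"practitioner_{level}"] = (df["practitioner_type"] == level).astype(int)
    if "acute_medication" in df:
        X["acute_medication"] = df["acute_medication"].astype(int)
    if "severity" in df:
        for level in ("major", "minor"):
            if (df["severity"] == level).any():
                X[f"severity_{level}"] = (df["severity"] == level).astype(int)
    if "male" in df:
        X["male"] = df["male"].astype(int)
    if "age_group" in df:
        for level in ("0-49", "50-64", "80+"):
            if (df["age_group"] == level).any():
                X[f"age_{level}"] = (df["age_group"] == level).astype(int)
    for col in sorted(c for c in df.columns if c.startswith("rxrisk_")):
        if df[col].any():
            X[col] = df[col].astype(int)
    return X


def fit_outcome_model(df: pd.DataFrame, outcome: str = "success") -> RegressionResult:
    """Fit the adjusted logistic model; raise on separation or non-convergence.

    ``df`` is one row per matched event with the outcome column plus the
    covariates understood by :func:`build_design_matrix`.
    """
    y = df[outcome].astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise StatsError("degenerate outcome: no variation in the outcome column")
    X = sm.add_constant(build_design_matrix(df), has_constant="add")
    try:
        fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise StatsError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise StatsError("logistic fit did not converge; check for separation or collinearity")
    if not np.isfinite(fit.bse).all():
        raise StatsError("non-finite standard errors; quasi-separation suspected")
    ci = fit.conf_int()
    return RegressionResult(
        terms=tuple(X.columns),
        coefficients=fit.params.to_numpy(),
        p_values=fit.pvalues.to_numpy(),
        odds_ratios=np.exp(fit.params.to_numpy()),
        ci_lower=np.exp(ci[0].to_numpy()),
        ci_upper=np.exp(ci[1].to_numpy()),
        converged=True,
        n_obs=len(y),
    )
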