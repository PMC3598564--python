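from __future__ import annotations

from datetime import date
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ddialert.stats import (StatsError, assign_rxrisk, build_design_matrix,
                            choose_test, compare_arms, expected_counts,
                            fit_outcome_model, load_rxrisk_map, pair_result,
                            pair_results_table)
from ddialert.synthetic_data import change_probability

from conftest import make_claim


def expected_by_hand(table):
    (a, b), (c, d) = table
    n = a + b + c + d
    rows, cols = (a + b, c + d), (a + c, b + d)
    return [[rows[i] * cols[j] / n for j in range(2)] for i in range(2)]


def fisher_enumeration(a, b, c, d):
    """Exhaustive two-sided Fisher: sum hypergeometric outcomes with point
    probability <= that of the observed table (relative tolerance as in the
    standard implementations)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    cutoff = probs[a - lo] * (1 + 1e-7)
    return sum(p for p in probs if p <= cutoff) / denom


class TestChooseTest:
    @pytest.mark.parametrize("table, expected", [
        ([[8, 4], [2, 10]], "fisher_exact"),      # min expected exactly 5.0
        ([[8, 161], [3, 166]], "chi_square"),     # min expected 5.5
        ([[55, 248], [48, 255]], "chi_square"),   # min expected 51.5
    ])
    def test_threshold_on_expected_counts(self, table, expected):
        assert np.allclose(expected_counts(table), expected_by_hand(table))
        assert choose_test(table) == expected

    def test_zero_margin_forces_exact_test(self):
        assert choose_test([[0, 10], [0, 12]]) == "fisher_exact"

    def test_all_zero_table_rejected(self):
        with pytest.raises(StatsError):
            compare_arms([[0, 0], [0, 0]])


class TestCompareArms:
    def test_pooled_counts_give_published_pooled_p(self):
        test, p = compare_arms([[154, 1865], [132, 1887]])
        assert test == "chi_square"
        assert round(p, 3) == 0.177

    def test_small_cohort_uses_fisher(self):
        test, p = compare_arms([[8, 4], [2, 10]])
        assert test == "fisher_exact"
        assert round(p, 2) == 0.04

    @pytest.mark.parametrize("k, m", [(3, 9), (10, 150), (0, 7)])
    def test_symmetric_table_is_null(self, k, m):
        _, p = compare_arms([[k, m], [k, m]])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_chi_square_invariant_under_swap_and_transpose(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(6, 80, size=(2, 2))
        while choose_test(t) != "chi_square":
            t = rng.integers(6, 80, size=(2, 2))
        _, p = compare_arms(t)
        for other in (t[::-1], t.T, t.T[::-1]):
            assert compare_arms(other)[1] == pytest.approx(p, rel=1e-12)

    @pytest.mark.parametrize("table", [
        (2, 9, 4, 7), (8, 4, 2, 10), (1, 61, 1, 61), (3, 4, 2, 5), (0, 5, 3, 2),
    ])
    def test_fisher_agrees_with_enumeration(self, table):
        a, b, c, d = table
        _, p = compare_arms([[a, b], [c, d]])
        assert p == pytest.approx(fisher_enumeration(a, b, c, d), rel=1e-8)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_p_values_are_probabilities_and_label_symmetric(self, cells):
        a, b, c, d = cells
        assume(a + b + c + d > 0)
        from ddialert.stats import fisher_two_sided

        test, p = compare_arms([[a, b], [c, d]])
        assert 0.0 <= p <= 1.0
        # swapping the arm labels cannot change the two-sided p-value
        test_swapped, p_swapped = compare_arms([[c, d], [a, b]])
        assert test_swapped == test
        assert p_swapped == pytest.approx(p, rel=1e-10)
        assert fisher_two_sided([[d, c], [b, a]]) == pytest.approx(
            fisher_two_sided([[a, b], [c, d]]), rel=1e-10)

    def test_pair_result_rates(self):
        res = pair_result("warfarin_fibrates", 303, 55, 48)
        assert res.rate_intervention == pytest.approx(55 / 303)
        assert res.rate_control == pytest.approx(48 / 303)
        assert res.test_used == "chi_square"


class TestRxRisk:
    def test_ssri_claim_flags_depression(self):
        flags = assign_rxrisk(
            [make_claim(drug="sertraline", fill=date(2010, 4, 1))],
            load_rxrisk_map(), index_date=date(2010, 5, 1))
        assert flags["depression"]
        assert not flags["diabetes"]

    def test_no_claims_all_false(self):
        flags = assign_rxrisk([], load_rxrisk_map(), index_date=date(2010, 5, 1))
        assert not any(flags.values())

    def test_flags_monotone_in_claims(self):
        cmap = load_rxrisk_map()
        base = [make_claim(drug="metformin", fill=date(2010, 4, 1))]
        more = base + [make_claim(drug="warfarin", fill=date(2010, 4, 2)),
                       make_claim(drug="unknown_drug", fill=date(2010, 4, 3))]
        f1 = assign_rxrisk(base, cmap, date(2010, 5, 1))
        f2 = assign_rxrisk(more, cmap, date(2010, 5, 1))
        assert all(f2[c] or not f1[c] for c in f1)

    def test_lookback_window_respected(self):
        cmap = load_rxrisk_map()
        old = [make_claim(drug="sertraline", fill=date(2009, 1, 1))]
        assert not assign_rxrisk(old, cmap, date(2010, 5, 1))["depression"]


def _simulate_outcome_frame(rng, n_per_arm, baseline, odds_ratio):
    p1 = change_probability(baseline, odds_ratio, True)
    p0 = change_probability(baseline, odds_ratio, False)
    return pd.DataFrame({
        "intervention": np.repeat([True, False], n_per_arm),
        "success": np.concatenate([
            rng.random(n_per_arm) < p1, rng.random(n_per_arm) < p0]),
    })


class TestOutcomeModel:
    def test_recovers_planted_intervention_odds_ratio(self):
        rng = np.random.default_rng(123)
        df = _simulate_outcome_frame(rng, 10000, baseline=0.10, odds_ratio=1.5)
        res = fit_outcome_model(df)
        term = res.term("intervention")
        assert term["or_ci_lower"] < 1.5 < term["or_ci_upper"]
        assert term["odds_ratio"] == pytest.approx(1.5, rel=0.25)

    def test_permutation_null_pvalues_uniform(self):
        # with the intervention label randomly permuted, the Wald p-value for
        # the intervention term must be uniform across replicates
        rng = np.random.default_rng(77)
        n = 800
        y = rng.random(n) < 0.15
        pvals = []
        for _ in range(200):
            df = pd.DataFrame({"intervention": rng.permutation(n) < n // 2,
                               "success": y})
            pvals.append(fit_outcome_model(df).term("intervention")["p_value"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_outcome_rejected(self):
        df = pd.DataFrame({"intervention": [True, False] * 10, "success": [False] * 20})
        with pytest.raises(StatsError, match="degenerate"):
            fit_outcome_model(df)

    def test_design_matrix_reference_levels_absent(self):
        df = pd.DataFrame({
            "intervention": [True, False, True, False],
            "practitioner_type": ["physician", "nurse_practitioner", "physician",
                                  "other"],
            "severity": ["moderate", "major", "minor", "moderate"],
            "age_group": ["65-79", "0-49", "80+", "50-64"],
            "male": [True, False, False, True],
        })
        X = build_design_matrix(df)
        assert "practitioner_physician" not in X.columns       # reference level
        assert "severity_moderate" not in X.columns
        assert "age_65-79" not in X.columns
        assert {"practitioner_nurse_practitioner", "severity_major", "age_0-49",
                "male"} <= set(X.columns)

    def test_separation_reported_not_silent(self):
        df = pd.DataFrame({"intervention": [True] * 12 + [False] * 12,
                           "success": [True] * 12 + [False] * 12})
        with pytest.raises(StatsError):
            fit_outcome_model(df)


class TestPairResultsTable:
    def test_total_row_pools_all_events(self, rules):
        from ddialert.outcomes import OutcomeRecord

        records = []
        for i in range(40):
            records.append(OutcomeRecord(f"e{i}", "warfarin_fibrates", f"p{i}",
                                         "intervention", i < 8,
                                         "ezetimibe" if i < 8 else None,
                                         10 if i < 8 else None))
            records.append(OutcomeRecord(f"f{i}", "warfarin_fibrates", f"q{i}",
                                         "control", i < 5,
                                         "pravastatin" if i < 5 else None,
                                         10 if i < 5 else None))
        table = pair_results_table(records)
        total = table[table.rule_id == "Total"].iloc[0]
        assert total.n_per_arm == 40
        assert total.changes_intervention == 8 and total.changes_control == 5
        assert table.iloc[0].rule_id == "warfarin_fibrates"

    def test_empty_records_empty_table(self):
        assert pair_results_table([]).empty
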