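from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from ddialert.claims_model import age_at
from ddialert.detection import detect_events
from ddialert.matching import cohort_summary, match_cohorts, period_key

from conftest import make_claim, make_data, make_patient, make_prescriber


def _event_population(rules_by_id, spec_rows, prefix):
    """Build patients + claims that yield one warfarin-fibrate event per row of
    (gender, birth_year, lob, fill_day)."""
    patients, claims = [], []
    for i, (gender, birth_year, lob, day) in enumerate(spec_rows):
        pid = f"{prefix}{i}"
        patients.append(make_patient(
            pid, birth=date(birth_year, 1, 1), gender=gender, lob=lob))
        fill = date(2010, 5, 1) + timedelta(days=day)
        claims.append(make_claim(patient=pid, drug="warfarin", fill=fill, supply=60,
                                 lob=lob))
        claims.append(make_claim(patient=pid, drug="gemfibrozil",
                                 fill=fill + timedelta(days=3), supply=30, lob=lob))
    data = make_data(patients, [make_prescriber()], claims)
    events = detect_events(data, [rules_by_id["warfarin_fibrates"]])
    return data, events


def max_bipartite_pairs(cases, controls, case_patients, control_patients, period="month"):
    """Brute-force maximum matching size via augmenting paths (single-rule oracle)."""
    def compatible(cv, ct):
        pc, pt = case_patients[cv.patient_id], control_patients[ct.patient_id]
        return (cv.rule_id == ct.rule_id and pc.gender == pt.gender
                and pc.lob == pt.lob
                and period_key(cv.index_date, period) == period_key(ct.index_date, period)
                and abs(age_at(pc, cv.index_date) - age_at(pt, ct.index_date)) <= 2)

    adj = {i: [j for j, ct in enumerate(controls) if compatible(cv, ct)]
           for i, cv in enumerate(cases)}
    match_of_control: dict[int, int] = {}

    def augment(i, seen):
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if j not in match_of_control or augment(match_of_control[j], seen):
                match_of_control[j] = i
                return True
        return False

    return sum(augment(i, set()) for i in range(len(cases)))


class TestMatchCohorts:
    def test_compatible_single_pair(self, rules_by_id):
        data_i, cases = _event_population(rules_by_id, [("F", 1940, "commercial", 5)], "I")
        data_c, pool = _event_population(rules_by_id, [("F", 1941, "commercial", 12)], "C")
        pairs, unmatched = match_cohorts(cases, pool, data_i.patients, data_c.patients)
        assert len(pairs) == 1 and not unmatched
        assert abs(pairs[0].age_gap) <= 2

    def test_age_gap_over_two_years_unmatched(self, rules_by_id):
        data_i, cases = _event_population(rules_by_id, [("F", 1940, "commercial", 5)], "I")
        data_c, pool = _event_population(rules_by_id, [("F", 1943, "commercial", 12)], "C")
        pairs, unmatched = match_cohorts(cases, pool, data_i.patients, data_c.patients)
        assert not pairs and len(unmatched) == 1

    @pytest.mark.parametrize("mutate", ["gender", "lob", "period"])
    def test_stratum_mismatch_unmatched(self, rules_by_id, mutate):
        control_row = {
            "gender": ("M", 1940, "commercial", 12),
            "lob": ("F", 1940, "medicaid", 12),
            "period": ("F", 1940, "commercial", 45),  # next calendar month
        }[mutate]
        data_i, cases = _event_population(rules_by_id, [("F", 1940, "commercial", 5)], "I")
        data_c, pool = _event_population(rules_by_id, [control_row], "C")
        pairs, _ = match_cohorts(cases, pool, data_i.patients, data_c.patients)
        assert not pairs

    def test_greedy_equals_exhaustive_on_nearest_age_fixture(self, rules_by_id):
        # cases at distinct ages with controls one year off: nearest-age-first
        # greedy attains the optimal matching size
        rows_i = [("F", 1940 + k, "commercial", 5) for k in range(6)]
        rows_c = [("F", 1941 + k, "commercial", 10) for k in range(6)]
        data_i, cases = _event_population(rules_by_id, rows_i, "I")
        data_c, pool = _event_population(rules_by_id, rows_c, "C")
        pairs, _ = match_cohorts(cases, pool, data_i.patients, data_c.patients)
        optimum = max_bipartite_pairs(cases, pool, data_i.patients, data_c.patients)
        assert len(pairs) == optimum == 6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_greedy_never_beats_exhaustive_optimum(self, rules_by_id, seed):
        rng = np.random.default_rng(seed)
        def rows(n):
            return [
                ("F" if rng.random() < 0.5 else "M",
                 int(rng.integers(1930, 1950)), "commercial", int(rng.integers(0, 80)))
                for _ in range(n)
            ]
        data_i, cases = _event_population(rules_by_id, rows(10), "I")
        data_c, pool = _event_population(rules_by_id, rows(14), "C")
        pairs, unmatched = match_cohorts(cases, pool, data_i.patients, data_c.patients)
        optimum = max_bipartite_pairs(cases, pool, data_i.patients, data_c.patients)
        assert len(pairs) <= optimum
        assert len(pairs) + len(unmatched) == len(cases)

    def test_empty_pool_leaves_all_unmatched(self, rules_by_id, caplog):
        data_i, cases = _event_population(rules_by_id, [("F", 1940, "commercial", 5)], "I")
        with caplog.at_level("WARNING"):
            pairs, unmatched = match_cohorts(cases, [], data_i.patients, {})
        assert not pairs and len(unmatched) == 1
        assert "empty control pool" in caplog.text

    def test_control_patient_single_cohort_across_rules(self, rules_by_id):
        # one control patient exposed under two rules can only serve one cohort
        ctl = make_patient("C0", birth=date(1940, 1, 1), gender="F")
        claims = [
            make_claim(patient="C0", drug="warfarin", fill=date(2010, 5, 1), supply=90),
            make_claim(patient="C0", drug="gemfibrozil", fill=date(2010, 5, 5), supply=30),
            make_claim(patient="C0", drug="fluvastatin", fill=date(2010, 5, 6), supply=30),
        ]
        data_c = make_data([ctl], [make_prescriber()], claims)
        rules = [rules_by_id["warfarin_fibrates"], rules_by_id["warfarin_statins"]]
        pool = detect_events(data_c, rules)
        assert {e.rule_id for e in pool} == {r.rule_id for r in rules}

        rows = [("F", 1940, "commercial", 5)]
        data_f, fib_cases = _event_population(rules_by_id, rows, "I")
        # a warfarin+statin case in the same stratum
        ws = make_patient("W0", birth=date(1940, 1, 1), gender="F")
        ws_claims = [
            make_claim(patient="W0", drug="warfarin", fill=date(2010, 5, 1), supply=60),
            make_claim(patient="W0", drug="simvastatin", fill=date(2010, 5, 6), supply=30),
        ]
        data_w = make_data([ws], [make_prescriber()], ws_claims)
        stat_cases = detect_events(data_w, [rules_by_id["warfarin_statins"]])

        cases = fib_cases + stat_cases
        patients_i = {**data_f.patients, **data_w.patients}
        pairs, unmatched = match_cohorts(cases, pool, patients_i, data_c.patients)
        assert len(pairs) == 1 and len(unmatched) == 1

    def test_matching_invariant_to_input_order(self, rules_by_id):
        rng = np.random.default_rng(5)
        rows = [("F" if rng.random() < 0.5 else "M", int(rng.integers(1935, 1950)),
                 "commercial", int(rng.integers(0, 50))) for _ in range(12)]
        data_i, cases = _event_population(rules_by_id, rows, "I")
        data_c, pool = _event_population(rules_by_id, rows, "C")
        key = lambda p: (p.rule_id, p.intervention_event.patient_id,
                         p.control_event.patient_id)
        a, _ = match_cohorts(cases, pool, data_i.patients, data_c.patients)
        b, _ = match_cohorts(list(reversed(cases)), list(reversed(pool)),
                             data_i.patients, data_c.patients)
        assert sorted(map(key, a)) == sorted(map(key, b))


class TestCohortSummary:
    def test_counts_and_percentages(self, rules_by_id):
        rows = [("F", 1940, "commercial", 5), ("M", 1945, "commercial", 8)]
        data_i, cases = _event_population(rules_by_id, rows, "I")
        data_c, pool = _event_population(rules_by_id, rows, "C")
        pairs, _ = match_cohorts(cases, pool, data_i.patients, data_c.patients)
        table = cohort_summary(pairs)
        total = table[table.rule_id == "Total"]
        assert int(total.n_pairs.iloc[0]) == len(pairs)
        assert table[table.rule_id != "Total"].n_pairs.sum() == len(pairs)
        assert abs(table[table.rule_id != "Total"].pct_of_total.sum() - 100.0) < 1e-9

    def test_empty_pairs_all_zero(self):
        table = cohort_summary([])
        assert int(table.n_pairs.sum()) == 0
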