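"""Realism metrics: identity behaviour, hand-computed toys, oracle checks."""

import itertools
from collections import Counter
from datetime import datetime, timedelta

import numpy as np
import pytest

from ehrsynth.evaluate import (
    bigram_r2,
    code_frequency_r2,
    conditional_cohort_check,
    conditional_occurrence,
    correlation_fidelity,
    summary_compare,
)
from ehrsynth.records import PatientRecord, Visit
from ehrsynth.simulate import SimConfig, build_schema, simulate_cohort

from test_cohort import make_record, simple_schema


def visits_with_codes(code_sets, start=datetime(2019, 1, 7, 9)):
    return [
        Visit(start_time=start + timedelta(days=30 * i), event_type="ED",
              codes=set(cs))
        for i, cs in enumerate(code_sets)
    ]


class TestSummaryCompare:
    def test_identical_cohorts_identical_columns(self, sim_small):
        cfg, records, _ = sim_small
        schema = build_schema(cfg)
        table = summary_compare(records, records, schema)
        assert np.allclose(table["real"].astype(float),
                           table["synthetic"].astype(float), equal_nan=True)

    def test_single_patient_age_50(self):
        schema = simple_schema()
        rec = make_record("p", 1, age=50.0)
        table = summary_compare([rec], [rec], schema)
        assert table.loc["age_mean", "real"] == 50.0
        assert table.loc["age_sd", "real"] == 0.0

    def test_toy_cohort_hand_computed(self):
        schema = simple_schema()
        recs = [make_record("a", 1, age=30.0), make_record("b", 1, age=40.0),
                make_record("c", 2, age=50.0)]
        t = summary_compare(recs, recs, schema)
        assert t.loc["age_mean", "real"] == pytest.approx(40.0)
        assert t.loc["age_sd", "real"] == pytest.approx(10.0)
        assert t.loc["visits_median", "real"] == 1.0
        assert t.loc["pct_female", "real"] == 100.0
        assert t.loc["gap_days_median", "real"] == pytest.approx(7.0)


class TestCorrelationFidelity:
    def test_self_comparison_zero_difference(self, sim_small):
        cfg, records, _ = sim_small
        schema = build_schema(cfg)
        _, _, diff, mx = correlation_fidelity(
            records, records, schema,
            ["age", "total_los_hours", "treatment_los_hours"])
        assert mx == pytest.approx(0.0, abs=1e-12)

    def test_independent_variables_uncorrelated(self):
        records, _ = simulate_cohort(SimConfig(n_patients=1500, seed=8))
        schema = build_schema(SimConfig())
        corr, _, _, _ = correlation_fidelity(
            records, records, schema, ["age", "total_los_hours"])
        assert abs(corr.loc["age", "total_los_hours"]) < 0.05

    def test_linear_pair_has_unit_correlation(self):
        schema = simple_schema()
        recs = []
        for i in range(50):
            r = make_record(f"p{i}", 1, age=20.0 + i)
            r.visits[0].continuous["lab"] = 2.0 * (20.0 + i) + 1.0
            recs.append(r)
        corr, _, _, _ = correlation_fidelity(recs, recs, schema, ["age", "lab"])
        assert corr.loc["age", "lab"] == pytest.approx(1.0)

    def test_too_few_variables_rejected(self, sim_small):
        cfg, records, _ = sim_small
        with pytest.raises(ValueError):
            correlation_fidelity(records, records, build_schema(cfg), ["age"])


class TestCodeFrequencyR2:
    def test_identity(self, sim_small):
        _, records, _ = sim_small
        r2, retained = code_frequency_r2(records, records)
        assert r2 == pytest.approx(1.0)
        assert retained == 1.0

    def test_retained_fraction_counts_missing_codes(self):
        real = [PatientRecord("a", {}, visits_with_codes([{"A00", "B00", "C00", "D00"}]))]
        synth = [PatientRecord("b", {}, visits_with_codes([{"A00", "B00"}]))]
        _, retained = code_frequency_r2(real, synth)
        assert retained == 0.5

    def test_toy_r2_equals_hand_computed_least_squares(self):
        real = [PatientRecord("a", {}, visits_with_codes(
            [{"A"}, {"A"}, {"A"}, {"B"}, {"B"}, {"C"}]))]
        synth = [PatientRecord("b", {}, visits_with_codes(
            [{"A"}, {"A"}, {"B"}, {"B"}, {"B"}, {"C"}]))]
        r2, _ = code_frequency_r2(real, synth, log_scale=False)
        fr = np.array([3, 2, 1]) / 6
        fs = np.array([2, 3, 1]) / 6
        expected = 1.0 - ((fs - fr) ** 2).sum() / ((fr - fr.mean()) ** 2).sum()
        assert r2 == pytest.approx(expected)


def brute_force_bigrams(records, mode):
    """Independent exhaustive enumeration oracle."""
    probs = Counter()
    if mode == "within_visit":
        total = sum(len(r.visits) for r in records)
        for r in records:
            for v in r.visits:
                for a in v.codes:
                    for b in v.codes:
                        if a < b:
                            probs[(a, b)] += 1
    else:
        total = sum(len(r.visits) - 1 for r in records)
        for r in records:
            for i in range(len(r.visits) - 1):
                for a in r.visits[i].codes:
                    for b in r.visits[i + 1].codes:
                        probs[(a, b)] += 1
    return {k: v / total for k, v in probs.items()}


class TestBigramR2:
    def test_identity(self, sim_small):
        _, records, _ = sim_small
        assert bigram_r2(records, records, "within_visit") == pytest.approx(1.0)
        assert bigram_r2(records, records, "sequential_visits") == pytest.approx(1.0)

    @pytest.mark.parametrize("mode", ["within_visit", "sequential_visits"])
    def test_matches_enumeration_oracle_on_small_cohorts(self, mode):
        rng = np.random.default_rng(7)
        codes = ["A", "B", "C", "D"]
        real, synth = [], []
        for out, seed_off in ((real, 0), (synth, 100)):
            for i in range(6):
                sets = [set(rng.choice(codes, size=rng.integers(1, 4),
                                       replace=False))
                        for _ in range(int(rng.integers(2, 4)))]
                out.append(PatientRecord(f"p{i}", {}, visits_with_codes(sets)))
        from ehrsynth.evaluate.realism import _bigram_probs

        for cohort in (real, synth):
            assert _bigram_probs(cohort, mode) == pytest.approx(
                brute_force_bigrams(cohort, mode))
        # and the r2 itself agrees with one computed from the oracle tables
        pr, ps = brute_force_bigrams(real, mode), brute_force_bigrams(synth, mode)
        support = sorted(set(pr) | set(ps))
        x = np.array([pr.get(k, 0.0) for k in support])
        y = np.array([ps.get(k, 0.0) for k in support])
        expected = max(0.0, 1.0 - ((y - x) ** 2).sum()
                       / ((x - x.mean()) ** 2).sum())
        assert bigram_r2(real, synth, mode) == pytest.approx(expected)

    def test_disjoint_vocabularies_give_zero(self):
        real = [PatientRecord("a", {}, visits_with_codes([{"A", "B"}] * 3))]
        synth = [PatientRecord("b", {}, visits_with_codes([{"C", "D"}] * 3))]
        assert bigram_r2(real, synth, "within_visit") == 0.0

    def test_sequential_requires_multi_visit_patients(self):
        real = [PatientRecord("a", {}, visits_with_codes([{"A"}]))]
        with pytest.raises(ValueError):
            bigram_r2(real, real, "sequential_visits")


class TestConditionalOccurrence:
    def test_later_visit_hit_and_clean_patient(self):
        pa = PatientRecord("a", {}, visits_with_codes([{"IDX"}, set(), {"OUT"}]))
        pb = PatientRecord("b", {}, visits_with_codes([set(), set()]))
        p_with, p_without = conditional_occurrence([pa, pb], {"IDX"}, {"OUT"})
        assert (p_with, p_without) == (1.0, 0.0)

    def test_same_visit_outcome_does_not_count(self):
        pa = PatientRecord("a", {}, visits_with_codes([{"IDX", "OUT"}, set()]))
        p_with, _ = conditional_occurrence([pa], {"IDX"}, {"OUT"})
        assert p_with == 0.0

    def test_empty_code_sets_rejected(self):
        with pytest.raises(ValueError):
            conditional_occurrence([], set(), {"A"})


class TestConditionalCohortCheck:
    def test_full_prevalence_when_every_patient_has_code(self):
        cohort = [PatientRecord(f"p{i}", {"age": 70.0, "gender": "F"},
                                visits_with_codes([{"E11.0"}]))
                  for i in range(5)]
        out = conditional_cohort_check(cohort, cohort, cohort, {"E11.0"})
        assert out["prevalence_conditioned"] == 1.0
        assert out["conditioned_profile"]["mean_age"] == 70.0

    def test_unconditioned_equals_real(self, sim_small):
        _, records, _ = sim_small
        out = conditional_cohort_check(records, records, records, {"E11.0", "E11.9"})
        assert out["prevalence_unconditioned"] == out["prevalence_real"]

    def test_empty_conditioned_cohort_rejected(self, sim_small):
        _, records, _ = sim_small
        with pytest.raises(ValueError):
            conditional_cohort_check([], records, records, {"E11.0"})
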