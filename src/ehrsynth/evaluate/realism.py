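"""Realism metrics: distributions, correlations, code frequencies and
co-occurrence structure compared between a real and a synthetic cohort."""

from __future__ import annotations

import itertools
import math
from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..cohort import gap_days
from ..records import PatientRecord
from ..schema import CohortSchema


def _visit_frame(records: Sequence[PatientRecord], schema: CohortSchema,
                 variables: Sequence[str]) -> pd.DataFrame:
    """One row per visit with patient statics joined and gap_days derived."""
    rows = []
    for rec in records:
        base = {"patient_id": rec.patient_id, "n_visits": len(rec.visits)}
        for k, v in rec.statics.items():
            base[k] = v
        prev = None
        for v in rec.visits:
            row = dict(base)
            row["event_type"] = v.event_type
            for k, val in v.continuous.items():
                row[k] = val
            for k, val in v.categoricals.items():
                row.setdefault(k, val)
            row["gap_days"] = gap_days(prev, v, schema) if prev is not None else np.nan
            prev = v
            rows.append(row)
    df = pd.DataFrame(rows)
    for var in variables:
        if var not in df.columns:
            df[var] = np.nan
    return df


def summary_compare(real: Sequence[PatientRecord], synth: Sequence[PatientRecord],
                    schema: CohortSchema,
                    variables: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Side-by-side descriptive statistics (mean/sd, median/IQR/range,
    % female, visits per patient, days between visits, unique codes)."""
    variables = list(variables or [f.name for f in schema.continuous_visit_fields])

    def one(records, label):
        stats = {}
        ages = [r.statics.get("age") for r in records
                if isinstance(r.statics.get("age"), (int, float))]
        if ages:
            stats["age_mean"] = float(np.mean(ages))
            stats["age_sd"] = float(np.std(ages, ddof=1)) if len(ages) > 1 else 0.0
        genders = [r.statics.get("gender") for r in records if r.statics.get("gender")]
        if genders:
            stats["pct_female"] = 100.0 * np.mean([g == "F" for g in genders])
        nv = [len(r.visits) for r in records]
        q1, q3 = np.percentile(nv, [25, 75])
        stats.update(visits_median=float(np.median(nv)), visits_iqr_low=float(q1),
                     visits_iqr_high=float(q3), visits_min=float(np.min(nv)),
                     visits_max=float(np.max(nv)))
        gaps = [g for r in records
                for g in (gap_days(a, b, schema) for a, b in zip(r.visits, r.visits[1:]))
                if g is not None]
        if gaps:
            q1, q3 = np.percentile(gaps, [25, 75])
            stats.update(gap_days_median=float(np.median(gaps)),
                         gap_days_iqr_low=float(q1), gap_days_iqr_high=float(q3),
                         gap_days_min=float(np.min(gaps)), gap_days_max=float(np.max(gaps)))
        for var in variables:
            vals = [v.continuous[var] for r in records for v in r.visits
                    if var in v.continuous]
            if not vals:
                continue
            q1, q3 = np.percentile(vals, [25, 75])
            stats.update({
                f"{var}_mean": float(np.mean(vals)),
                f"{var}_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                f"{var}_median": float(np.median(vals)),
                f"{var}_iqr_low": float(q1), f"{var}_iqr_high": float(q3),
            })
        stats["unique_codes"] = len({c for r in records for v in r.visits for c in v.codes})
        return pd.Series(stats, name=label)

    return pd.concat([one(real, "real"), one(synth, "synthetic")], axis=1)


def correlation_fidelity(real, synth, schema: CohortSchema,
                         variables: Sequence[str]):
    """Pairwise Pearson correlations on visit rows, plus the difference
    matrix and its largest absolute entry."""
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    fr = _visit_frame(real, schema, variables)[list(variables)]
    fs = _visit_frame(synth, schema, variables)[list(variables)]
    corr_real = fr.corr(method="pearson")
    corr_synth = fs.corr(method="pearson")
    diff = corr_synth - corr_real
    max_abs = float(np.nanmax(np.abs(diff.values))) if diff.size else float("nan")
    return corr_real, corr_synth, diff, max_abs


def _code_counts(records) -> tuple[Counter, int]:
    c: Counter = Counter()
    for r in records:
        for v in r.visits:
            c.update(v.codes)
    return c, sum(c.values())


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Agreement R^2 against the identity line (real values as truth).

    1 - SS_res/SS_tot with the synthetic vector as the prediction of the
    real one; perfect agreement gives 1, disagreement beyond the trivial
    mean predictor is floored at 0.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    ss_tot = float(((x - x.mean()) ** 2).sum())
    if ss_tot == 0:
        return float(np.allclose(x, y))
    ss_res = float(((y - x) ** 2).sum())
    return max(0.0, 1.0 - ss_res / ss_tot)


def code_frequency_r2(real, synth, log_scale: bool = True) -> tuple[float, float]:
    """R^2 of per-code relative frequencies over codes present in real data
    (absent-in-synth codes enter at frequency zero), plus the fraction of
    real codes retained in the synthetic cohort."""
    cr, nr = _code_counts(real)
    cs, ns = _code_counts(synth)
    if nr == 0 or ns == 0:
        raise ValueError("empty code sets")
    codes = sorted(cr)
    fr = np.array([cr[c] / nr for c in codes])
    fs = np.array([cs.get(c, 0) / ns for c in codes])
    if log_scale:
        floor_r, floor_s = 0.5 / nr, 0.5 / ns
        fr = np.log10(np.maximum(fr, floor_r))
        fs = np.log10(np.maximum(fs, floor_s))
    retained = np.mean([c in cs for c in codes])
    return _r2(fr, fs), float(retained)


def _bigram_probs(records, mode: str) -> dict:
    if mode == "within_visit":
        pairs: Counter = Counter()
        total = 0
        for r in records:
            for v in r.visits:
                total += 1
                for a, b in itertools.combinations(sorted(v.codes), 2):
                    pairs[(a, b)] += 1
        return {k: v / total for k, v in pairs.items()} if total else {}
    if mode == "sequential_visits":
        pairs = Counter()
        total = 0
        for r in records:
            for va, vb in zip(r.visits, r.visits[1:]):
                total += 1
                for a in va.codes:
                    for b in vb.codes:
                        pairs[(a, b)] += 1
        if total == 0:
            raise ValueError("no multi-visit patients for sequential bigrams")
        return {k: v / total for k, v in pairs.items()}
    raise ValueError(f"unknown bigram mode {mode!r}")


def bigram_r2(real, synth, mode: str = "within_visit") -> float:
    """R^2 between diagnosis-code bigram probabilities.

    ``within_visit``: unordered pairs per visit, normalized by visit count;
    ``sequential_visits``: ordered pairs across consecutive visits,
    normalized by consecutive-pair count.  Computed on the union support.
    """
    pr = _bigram_probs(real, mode)
    ps = _bigram_probs(synth, mode)
    support = sorted(set(pr) | set(ps))
    if not support:
        return float("nan")
    x = np.array([pr.get(k, 0.0) for k in support])
    y = np.array([ps.get(k, 0.0) for k in support])
    return _r2(x, y)


def conditional_occurrence(records, index_dx_set, outcome_dx_set
                           ) -> tuple[float, float]:
    """P(outcome in any later visit | index diagnosis) vs. P(outcome ever |
    no index diagnosis)."""
    index_dx_set, outcome_dx_set = set(index_dx_set), set(outcome_dx_set)
    if not index_dx_set or not outcome_dx_set:
        raise ValueError("code sets must be nonempty")
    n_with = n_without = hit_with = hit_without = 0
    for r in records:
        first = next((j for j, v in enumerate(r.visits) if v.codes & index_dx_set), None)
        if first is not None:
            n_with += 1
            hit_with += any(v.codes & outcome_dx_set for v in r.visits[first + 1 :])
        else:
            n_without += 1
            hit_without += any(v.codes & outcome_dx_set for v in r.visits)
    p_with = hit_with / n_with if n_with else float("nan")
    p_without = hit_without / n_without if n_without else float("nan")
    return p_with, p_without


def conditional_cohort_check(synth_conditioned, synth_unconditioned, real,
                             condition_code_set) -> dict:
    """Prevalence of a condition in the three cohorts plus a demographic
    profile of the conditioned cohort against real patients having it."""
    cset = set(condition_code_set)
    if not cset:
        raise ValueError("condition code set must be nonempty")
    if not synth_conditioned:
        raise ValueError("empty conditioned cohort")

    def has(r):
        return any(v.codes & cset for v in r.visits)

    def prevalence(records):
        return float(np.mean([has(r) for r in records])) if records else float("nan")

    def profile(records):
        if not records:
            return {"mean_age": float("nan"), "pct_female": float("nan"),
                    "median_visits": float("nan")}
        ages = [r.statics.get("age") for r in records
                if isinstance(r.statics.get("age"), (int, float))]
        return {
            "mean_age": float(np.mean(ages)) if ages else float("nan"),
            "pct_female": 100.0 * float(np.mean(
                [r.statics.get("gender") == "F" for r in records])),
            "median_visits": float(np.median([len(r.visits) for r in records])),
        }

    real_with = [r for r in real if has(r)]
    return {
        "prevalence_conditioned": prevalence(synth_conditioned),
        "prevalence_unconditioned": prevalence(synth_unconditioned),
        "prevalence_real": prevalence(real),
        "conditioned_profile": profile(synth_conditioned),
        "real_condition_profile": profile(real_with),
    }
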