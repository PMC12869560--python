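"""Ground-truth cohort simulator.

Stands in for restricted clinical data: every statistical feature the
pipeline is meant to preserve — irregular visit timing with day-of-week and
seasonal intensity, heterogeneous visit counts, code co-occurrence and
progression structure, a correlated continuous pair, demographic-dependent
prevalence, informative missingness, small negative inter-visit overlaps —
is planted with known parameters, so each downstream stage and metric has a
recoverable truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .records import PatientRecord, Visit
from .schema import (
    BINARY_LABEL,
    CATEGORICAL,
    CONTINUOUS,
    CodeSystemSpec,
    CohortSchema,
    FieldSpec,
)


@dataclass
class CodeSpec:
    """Per-visit Bernoulli prevalence with optional demographic effects.

    ``age_beta`` shifts the log-odds by ``age_beta * (age - 50) / 10``;
    ``male_odds`` multiplies the odds for male patients.
    """

    code: str
    base_prevalence: float
    age_beta: float = 0.0
    male_odds: float = 1.0

    def prob(self, age: float, is_male: bool) -> float:
        logit = math.log(self.base_prevalence / (1 - self.base_prevalence))
        logit += self.age_beta * (age - 50.0) / 10.0
        if is_male:
            logit += math.log(self.male_odds)
        return 1.0 / (1.0 + math.exp(-logit))


@dataclass
class ProgressionRule:
    """Index-code family -> later-visit outcome code with fixed probability.

    Index codes are only planted in non-final visits, so a strictly later
    visit always exists and the conditional-occurrence estimand equals
    ``probability`` exactly.
    """

    index_codes: tuple[str, ...]
    outcome_code: str
    probability: float


@dataclass
class EventTypeSpec:
    name: str
    weight: float                       # event-type mixture weight
    dow_weights: tuple[float, ...]      # Mon..Sun visit-intensity weights
    los_meanlog: float                  # log-normal length of stay (hours)
    los_sdlog: float
    treat_meanlog: float                # correlated treatment LOS (hours)
    treat_sdlog: float


def _copula_rho(target_r: float, s1: float, s2: float) -> float:
    """Log-scale Gaussian-copula correlation giving a value-scale Pearson
    ``target_r`` for a bivariate log-normal pair."""

    def f(rho):
        num = math.exp(rho * s1 * s2) - 1.0
        den = math.sqrt((math.exp(s1 * s1) - 1.0) * (math.exp(s2 * s2) - 1.0))
        return num / den - target_r

    return float(optimize.brentq(f, -0.999, 0.999))


@dataclass
class SimConfig:
    n_patients: int = 2000
    seed: int = 0
    study_start: date = date(2018, 1, 1)
    study_end: date = date(2020, 12, 31)
    # demographics
    age_mean: float = 50.0
    age_sd: float = 18.0
    age_range: tuple[float, float] = (18.0, 90.0)
    female_prop: float = 0.5
    # visit process
    visit_rate: float = 2.5             # visits = 1 + Poisson(rate), capped
    max_visits: int = 10
    seasonal_amplitude: float = 0.3     # weekly intensity 1 + A*sin(2*pi*w/52)
    overlap_prob: float = 0.02          # next start pulled before prev end
    hour_weights: tuple[float, ...] = (
        1, 1, 1, 1, 1, 2, 4, 8, 12, 12, 12, 12, 10, 10, 10, 10, 10, 10, 8, 6, 4, 3, 2, 1,
    )
    event_types: tuple[EventTypeSpec, ...] = (
        EventTypeSpec("ED", 0.6, (2, 2, 2, 2, 2, 1, 1), 1.2, 0.7, 0.6, 0.7),
        EventTypeSpec("IP", 0.4, (2, 2, 2, 2, 2, 1, 1), 3.2, 1.0, 2.5, 0.8),
    )
    pair_target_r: float = 0.7          # total vs treatment LOS, value scale
    # codes
    codes: tuple[CodeSpec, ...] = (
        CodeSpec("E11.0", 0.04),
        CodeSpec("E11.9", 0.06),
        CodeSpec("I21.0", 0.03, age_beta=0.8),
        CodeSpec("I21.9", 0.02, age_beta=0.8),
        CodeSpec("J45.1", 0.05, age_beta=-0.8),
        CodeSpec("J45.9", 0.04),
        CodeSpec("I63.0", 0.02, age_beta=1.0),
        CodeSpec("F10.1", 0.03, male_odds=3.0),
        CodeSpec("C50.1", 0.015),
        CodeSpec("G30.0", 0.01, age_beta=1.6),
        CodeSpec("R07.4", 0.10),
        CodeSpec("K52.1", 0.03),
        # rare codes exercising prefix aggregation
        CodeSpec("E11.3", 0.003),
        CodeSpec("I21.4", 0.002),
        CodeSpec("J45.2", 0.003),
        CodeSpec("Z99.1", 0.002),
        CodeSpec("Z99.8", 0.003),
        CodeSpec("K52.8", 0.002),
    )
    outcome_code: str = "E16.0"         # progression-only (hypoglycaemia-like)
    cooccurrence: tuple[tuple[str, str, float], ...] = (("R07.4", "I21.0", 3.0),)
    progression: ProgressionRule = field(
        default_factory=lambda: ProgressionRule(("E11.0", "E11.9"), "E16.0", 0.6)
    )
    index_nonfinal_only: bool = True
    # missingness (rate; optional (code, multiplier) makes it informative)
    missing_rates: dict = field(
        default_factory=lambda: {"total_los_hours": 0.08, "treatment_los_hours": 0.12}
    )
    informative_missing: dict = field(
        default_factory=lambda: {"treatment_los_hours": ("G30.0", 2.5)}
    )
    # static condition labels from code-family prefixes
    label_rules: dict = field(
        default_factory=lambda: {"diabetes_label": "E11", "heart_label": "I21"}
    )
    # optional linear outcome: score = a + b*age + noise (visit level)
    linear_outcome: Optional[tuple[float, float, float]] = None  # (a, b, sd)
    has_end_times: bool = True

    def validate(self) -> None:
        for cs in self.codes:
            if not 0 < cs.base_prevalence < 1:
                raise ValueError(f"prevalence out of (0,1) for {cs.code}")
        for a, b, lift in self.cooccurrence:
            base = next(c for c in self.codes if c.code == b).base_prevalence
            if lift * base >= 1:
                raise ValueError(f"lift {lift} forces P({b})>=1")
        if not 0 <= self.female_prop <= 1:
            raise ValueError("female_prop out of range")
        if abs(self.pair_target_r) >= 1:
            raise ValueError("|pair_target_r| must be < 1")
        for et in self.event_types:
            if min(et.dow_weights) < 0 or max(et.dow_weights) == 0:
                raise ValueError("day-of-week weights must be nonnegative, not all zero")
        if self.max_visits < 1 or self.n_patients < 1:
            raise ValueError("sizes must be positive")


def build_schema(config: SimConfig) -> CohortSchema:
    """Schema matching the simulator's three-table output (bands unresolved)."""
    vocab = sorted({c.code for c in config.codes} | {config.outcome_code})
    statics = [
        FieldSpec("gender", CATEGORICAL, levels=["F", "M"]),
        FieldSpec("age", CONTINUOUS, n_bands=12),
    ]
    for lab in config.label_rules:
        statics.append(FieldSpec(lab, BINARY_LABEL))
    visit_fields = [
        FieldSpec("event_type", CATEGORICAL, levels=[e.name for e in config.event_types]),
        FieldSpec("disposition", CATEGORICAL, levels=["home", "admitted", "died"]),
    ]
    if config.has_end_times:
        visit_fields += [
            FieldSpec("total_los_hours", CONTINUOUS, n_bands=15),
            FieldSpec("treatment_los_hours", CONTINUOUS, n_bands=12),
        ]
    if config.linear_outcome is not None:
        visit_fields.append(FieldSpec("score", CONTINUOUS, n_bands=12))
    return CohortSchema(
        static_fields=statics,
        visit_fields=visit_fields,
        code_systems=[CodeSystemSpec("dx", vocab)],
        gap_field=FieldSpec("gap_days", CONTINUOUS),
        max_visits=config.max_visits,
        event_types=[e.name for e in config.event_types],
        has_end_times=config.has_end_times,
        study_start=config.study_start,
        study_end=config.study_end,
    )


def _monday_of(d: date) -> date:
    return d - timedelta(days=d.weekday())


def simulate_cohort(config: SimConfig, rng: Optional[np.random.Generator] = None
                    ) -> tuple[list[PatientRecord], dict]:
    """Draw a cohort and return it with a truth record of all parameters."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    week0 = _monday_of(config.study_start)
    n_weeks = int((config.study_end - week0).days // 7)
    weeks = np.arange(n_weeks)
    season = 1.0 + config.seasonal_amplitude * np.sin(2 * np.pi * weeks / 52.0)
    season = np.clip(season, 1e-9, None)
    week_p = season / season.sum()
    hour_p = np.asarray(config.hour_weights, float)
    hour_p = hour_p / hour_p.sum()
    et_weights = np.array([e.weight for e in config.event_types], float)
    et_p = et_weights / et_weights.sum()
    dow_p = {e.name: np.asarray(e.dow_weights, float) / sum(e.dow_weights)
             for e in config.event_types}
    et_by_name = {e.name: e for e in config.event_types}
    rho = {
        e.name: _copula_rho(config.pair_target_r, e.los_sdlog, e.treat_sdlog)
        for e in config.event_types
    }
    a, b = config.age_range
    tn = stats.truncnorm(
        (a - config.age_mean) / config.age_sd, (b - config.age_mean) / config.age_sd,
        loc=config.age_mean, scale=config.age_sd,
    )
    disp_levels, disp_p = ["home", "admitted", "died"], [0.90, 0.08, 0.02]
    code_specs = list(config.codes)
    cooc = {(a_, b_): lift for a_, b_, lift in config.cooccurrence}

    records = []
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        age = float(tn.ppf(rng.uniform(1e-9, 1 - 1e-9)))
        is_female = rng.uniform() < config.female_prop
        k = 1 + int(rng.poisson(config.visit_rate))
        k = min(k, config.max_visits)

        # visit dates: seasonally weighted week, per-event-type day of week
        etypes = [config.event_types[j].name for j in rng.choice(len(et_p), size=k, p=et_p)]
        starts = []
        for et in etypes:
            w = int(rng.choice(n_weeks, p=week_p))
            d = int(rng.choice(7, p=dow_p[et]))
            h = int(rng.choice(24, p=hour_p))
            starts.append(
                datetime.combine(week0 + timedelta(days=7 * w + d), datetime.min.time())
                + timedelta(hours=h, minutes=int(rng.integers(0, 60)))
            )
        order = np.argsort(np.array([s.timestamp() for s in starts], float), kind="stable")
        starts = [starts[j] for j in order]
        etypes = [etypes[j] for j in order]

        visits = []
        prev_end = None
        for j in range(k):
            et = et_by_name[etypes[j]]
            z1, z2 = rng.standard_normal(2)
            z2 = rho[et.name] * z1 + math.sqrt(1 - rho[et.name] ** 2) * z2
            total = math.exp(et.los_meanlog + et.los_sdlog * z1)
            treat = math.exp(et.treat_meanlog + et.treat_sdlog * z2)
            start = starts[j]
            if prev_end is not None and rng.uniform() < config.overlap_prob:
                # overlap bounded by the previous stay so visit order holds
                prev_span_days = (prev_end - visits[-1].start_time).total_seconds() / 86400
                start = prev_end - timedelta(
                    days=float(rng.uniform(0, min(2.0, max(prev_span_days, 0.0))))
                )
            elif prev_end is not None and start < prev_end:
                # keep non-overlap draws consistent with the anchor
                start = prev_end + timedelta(hours=float(rng.uniform(1, 48)))
            v = Visit(
                start_time=start,
                end_time=start + timedelta(hours=total) if config.has_end_times else None,
                event_type=et.name,
                categoricals={
                    "event_type": et.name,
                    "disposition": str(rng.choice(disp_levels, p=disp_p)),
                },
            )
            if config.has_end_times:
                v.continuous["total_los_hours"] = total
                v.continuous["treatment_los_hours"] = treat
            if config.linear_outcome is not None:
                a0, b0, sd0 = config.linear_outcome
                v.continuous["score"] = a0 + b0 * age + sd0 * rng.standard_normal()
            prev_end = v.end_time if v.end_time is not None else v.start_time
            visits.append(v)

        # codes: base prevalence with demographic effects + co-occurrence lift
        for j, v in enumerate(visits):
            for cs in code_specs:
                p = cs.prob(age, not is_female)
                if config.index_nonfinal_only and cs.code in config.progression.index_codes:
                    if j == len(visits) - 1:
                        continue
                p_eff = p
                for (ca, cb), lift in cooc.items():
                    if cs.code == cb and ca in v.codes:
                        p_eff = min(lift * p, 0.99)
                if rng.uniform() < p_eff:
                    v.codes.add(cs.code)
        # progression: outcome planted strictly after the first index visit
        idx_visits = [
            j for j, v in enumerate(visits)
            if v.codes & set(config.progression.index_codes)
        ]
        if idx_visits and idx_visits[0] < len(visits) - 1:
            if rng.uniform() < config.progression.probability:
                j = int(rng.integers(idx_visits[0] + 1, len(visits)))
                visits[j].codes.add(config.progression.outcome_code)

        # informative missingness
        for name, rate in config.missing_rates.items():
            trigger = config.informative_missing.get(name)
            for v in visits:
                r = rate
                if trigger and trigger[0] in v.codes:
                    r = min(rate * trigger[1], 1.0)
                if name in v.continuous and rng.uniform() < r:
                    del v.continuous[name]

        statics: dict = {"gender": "F" if is_female else "M", "age": age}
        all_codes = set().union(*(v.codes for v in visits))
        for lab, prefix in config.label_rules.items():
            statics[lab] = any(c.startswith(prefix) for c in all_codes)
        rec = PatientRecord(pid, statics, visits)
        rec.sort_visits()
        records.append(rec)

    dw = np.asarray(config.event_types[0].dow_weights, float)
    truth = {
        "n_patients": config.n_patients,
        "female_prop": config.female_prop,
        "age_mean": float(tn.mean()),
        "age_sd": float(tn.std()),
        "visit_rate": config.visit_rate,
        "pair_target_r": config.pair_target_r,
        "progression_probability": config.progression.probability,
        "progression_index": list(config.progression.index_codes),
        "progression_outcome": config.progression.outcome_code,
        "weekday_weekend_ratio": float(dw[:5].mean() / dw[5:].mean()),
        "seasonal_amplitude": config.seasonal_amplitude,
        "base_prevalence": {c.code: c.base_prevalence for c in config.codes},
        "overlap_prob": config.overlap_prob,
    }
    return records, truth


# ---------------------------------------------------------------------------
# truth recovery
# ---------------------------------------------------------------------------


def truth_check(records: list[PatientRecord], truth: dict) -> dict:
    """Re-estimate configured parameters and compare to Monte-Carlo tolerances.

    Returns ``{name: {estimate, truth, tol, ok}}``; tolerances are ~3 standard
    errors at the realized sample size.
    """
    out = {}
    n = len(records)

    def entry(name, est, tru, tol):
        out[name] = {
            "estimate": float(est),
            "truth": float(tru),
            "tol": float(tol),
            "ok": bool(abs(est - tru) <= tol),
        }

    female = np.mean([r.statics.get("gender") == "F" for r in records])
    entry("female_prop", female, truth["female_prop"], 3 * math.sqrt(0.25 / n))

    ages = np.array([r.statics["age"] for r in records], float)
    entry("age_mean", ages.mean(), truth["age_mean"], 3 * truth["age_sd"] / math.sqrt(n))

    # base prevalence of a plain code (no demographic/co-occurrence effects)
    plain = "J45.9"
    vis_n = sum(len(r.visits) for r in records)
    prev = sum(plain in v.codes for r in records for v in r.visits) / vis_n
    p0 = truth["base_prevalence"][plain]
    entry(f"prevalence[{plain}]", prev, p0, 3 * math.sqrt(p0 * (1 - p0) / vis_n))

    # progression probability
    idx = set(truth["progression_index"])
    outc = truth["progression_outcome"]
    with_idx, hits = 0, 0
    for r in records:
        first = next((j for j, v in enumerate(r.visits) if v.codes & idx), None)
        if first is None:
            continue
        with_idx += 1
        hits += any(outc in v.codes for v in r.visits[first + 1 :])
    if with_idx:
        p = truth["progression_probability"]
        entry("progression_probability", hits / with_idx, p,
              3 * math.sqrt(p * (1 - p) / with_idx) + 0.01)

    # correlated pair (IP stratum; complete pairs only)
    xs, ys = [], []
    for r in records:
        for v in r.visits:
            if v.event_type == "IP" and "total_los_hours" in v.continuous \
                    and "treatment_los_hours" in v.continuous:
                xs.append(v.continuous["total_los_hours"])
                ys.append(v.continuous["treatment_los_hours"])
    if len(xs) > 10:
        r_est = float(np.corrcoef(xs, ys)[0, 1])
        # Fisher-z tolerance (log-normal pairs converge slower than normal)
        tol = 3 * (1 - truth["pair_target_r"] ** 2) / math.sqrt(len(xs) - 3) + 0.05
        entry("pair_r", r_est, truth["pair_target_r"], tol)

    # weekday:weekend intensity ratio
    dows = np.array([v.start_time.weekday() for r in records for v in r.visits])
    wd = np.mean(dows < 5) / 5.0
    we = np.mean(dows >= 5) / 2.0
    ratio = wd / we if we > 0 else np.inf
    entry("weekday_weekend_ratio", ratio, truth["weekday_weekend_ratio"],
          0.25 * truth["weekday_weekend_ratio"])

    # seasonal amplitude from weekly counts via a sinusoid fit
    dates = [v.start_time.date() for r in records for v in r.visits]
    week0 = _monday_of(min(dates))
    wk = np.array([(d - week0).days // 7 for d in dates])
    counts = np.bincount(wk)
    t = np.arange(len(counts))
    X = np.column_stack([np.ones_like(t), np.sin(2 * np.pi * t / 52.0),
                         np.cos(2 * np.pi * t / 52.0)])
    beta, *_ = np.linalg.lstsq(X, counts, rcond=None)
    amp = math.hypot(beta[1], beta[2]) / beta[0] if beta[0] > 0 else 0.0
    entry("seasonal_amplitude", amp, truth["seasonal_amplitude"],
          0.1 + 0.3 * truth["seasonal_amplitude"])

    out["all_ok"] = all(v["ok"] for k, v in out.items() if isinstance(v, dict))
    return out


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
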