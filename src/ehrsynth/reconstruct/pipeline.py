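"""Fit-and-apply reconstruction state.

``fit_reconstruction`` learns everything the post-processing step needs
from training records — per-variable stratified KDE grids, an optional
joint grid for a correlated pair, calendar maps, empirical fallback tables
and the code aggregation map — and serializes it to a JSON sidecar.
``reconstruct_cohort`` turns generated banded skeletons into fully dated,
full-resolution patient records.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

from ..cohort import POOLED, CodeAggregationMap
from ..records import PatientRecord, PatientSkeleton, Visit
from ..schema import CONTINUOUS, CohortSchema
from .calendar import (
    HOURS_PER_DAY,
    CalendarMaps,
    derive_discharge,
    derive_next_admission,
    fit_calendar_maps,
    reconstruct_visit_dates,
)
from .codes import expand_codes
from .kde import (
    KdeGrid,
    fit_joint_kde,
    fit_marginal_kde,
    sample_joint_within_bands,
    sample_within_band,
)

FORMAT = "ehrsynth-reconstruction-v1"


@dataclass
class ReconstructionState:
    calendar: CalendarMaps
    marginals: dict = field(default_factory=dict)     # var -> KdeGrid
    gap_grid: Optional[KdeGrid] = None
    joint: Optional[KdeGrid] = None
    joint_pair: Optional[tuple[str, str]] = None
    aggregation: Optional[CodeAggregationMap] = None
    # empirical fallback tables
    static_level_probs: dict = field(default_factory=dict)
    visit_level_probs: dict = field(default_factory=dict)
    gap_band_probs: Optional[list[float]] = None
    end_hour_probs: Optional[list[float]] = None
    end_dow_probs: Optional[list[float]] = None
    flags: Counter = field(default_factory=Counter)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        d = {
            "format": FORMAT,
            "calendar": self.calendar.to_dict(),
            "marginals": {k: g.to_dict() for k, g in self.marginals.items()},
            "gap_grid": self.gap_grid.to_dict() if self.gap_grid else None,
            "joint": self.joint.to_dict() if self.joint else None,
            "joint_pair": list(self.joint_pair) if self.joint_pair else None,
            "aggregation": self.aggregation.to_dict() if self.aggregation else None,
            "static_level_probs": self.static_level_probs,
            "visit_level_probs": self.visit_level_probs,
            "gap_band_probs": self.gap_band_probs,
            "end_hour_probs": self.end_hour_probs,
            "end_dow_probs": self.end_dow_probs,
        }
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def load(cls, path) -> "ReconstructionState":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format") != FORMAT:
            raise ValueError(f"unrecognized reconstruction sidecar: {path}")
        return cls(
            calendar=CalendarMaps.from_dict(d["calendar"]),
            marginals={k: KdeGrid.from_dict(g) for k, g in d["marginals"].items()},
            gap_grid=KdeGrid.from_dict(d["gap_grid"]) if d["gap_grid"] else None,
            joint=KdeGrid.from_dict(d["joint"]) if d["joint"] else None,
            joint_pair=tuple(d["joint_pair"]) if d["joint_pair"] else None,
            aggregation=CodeAggregationMap.from_dict(d["aggregation"])
            if d["aggregation"] else None,
            static_level_probs=d["static_level_probs"],
            visit_level_probs=d["visit_level_probs"],
            gap_band_probs=d["gap_band_probs"],
            end_hour_probs=d["end_hour_probs"],
            end_dow_probs=d["end_dow_probs"],
        )


def fit_reconstruction(
    records,
    schema: CohortSchema,
    aggregation: Optional[CodeAggregationMap] = None,
    joint_pair: Optional[tuple[str, str]] = None,
    stratify_by: str = "gender",
    min_stratum_n: int = 30,
) -> ReconstructionState:
    """Learn KDE grids, calendar maps and fallback tables from training data.

    Visit-level variables are stratified by ``(gender, event_type)``; static
    continuous variables by gender; the joint pair by event type.
    """
    from ..cohort import gap_days

    cal = fit_calendar_maps(records, schema, min_stratum_n=min_stratum_n)
    state = ReconstructionState(calendar=cal, aggregation=aggregation)

    if joint_pair is None and schema.has_end_times:
        names = {f.name for f in schema.continuous_visit_fields}
        if {"total_los_hours", "treatment_los_hours"} <= names:
            joint_pair = ("total_los_hours", "treatment_los_hours")

    # static continuous variables (e.g. age), stratified by gender
    for f in schema.static_fields:
        if f.kind != CONTINUOUS:
            continue
        vals, strat = [], []
        for rec in records:
            v = rec.statics.get(f.name)
            if isinstance(v, (int, float)):
                vals.append(float(v))
                strat.append(str(rec.statics.get(stratify_by, POOLED)))
        if vals:
            state.marginals[f.name] = fit_marginal_kde(
                vals, strat, grid_resolution=1.0,
                min_stratum_n=min_stratum_n, variable=f.name,
            )

    # visit continuous variables, stratified by gender x event type
    for f in schema.continuous_visit_fields:
        vals, strat = [], []
        for rec in records:
            g = str(rec.statics.get(stratify_by, POOLED))
            for v in rec.visits:
                if f.name in v.continuous:
                    vals.append(v.continuous[f.name])
                    strat.append((g, str(v.event_type)))
        if vals:
            res = 1.0 if (np.max(vals) - np.min(vals)) < 500 else None
            state.marginals[f.name] = fit_marginal_kde(
                vals, strat, grid_resolution=res, min_stratum_n=min_stratum_n,
                variable=f.name,
            )

    if joint_pair is not None:
        xs, ys, strat = [], [], []
        for rec in records:
            for v in rec.visits:
                if joint_pair[0] in v.continuous and joint_pair[1] in v.continuous:
                    xs.append(v.continuous[joint_pair[0]])
                    ys.append(v.continuous[joint_pair[1]])
                    strat.append(str(v.event_type))
        if xs:
            state.joint = fit_joint_kde(xs, ys, strat, variables=joint_pair,
                                        min_stratum_n=min_stratum_n)
            state.joint_pair = joint_pair

    # inter-visit gaps (pooled; hybrid day/week grid drives the bands)
    gaps = [g for rec in records
            for g in (gap_days(a, b, schema)
                      for a, b in zip(rec.visits, rec.visits[1:]))
            if g is not None]
    if gaps:
        state.gap_grid = fit_marginal_kde(
            gaps, None, grid_resolution=1.0, variable=schema.gap_field.name,
        )
        bands = np.array([schema.gap_field.band_of(g)[0] for g in gaps])
        counts = np.bincount(bands, minlength=schema.gap_field.n_defined_bands)
        state.gap_band_probs = (counts / counts.sum()).tolist()

    # empirical fallback tables
    for f in schema.static_fields:
        if f.levels:
            c = Counter(str(rec.statics.get(f.name)) for rec in records
                        if rec.statics.get(f.name) is not None)
            tot = sum(c.values())
            if tot:
                state.static_level_probs[f.name] = {k: v / tot for k, v in sorted(c.items())}
    for f in schema.categorical_visit_fields:
        c = Counter(
            str(v.categoricals.get(f.name)) for rec in records for v in rec.visits
            if v.categoricals.get(f.name) is not None
        )
        tot = sum(c.values())
        if tot:
            state.visit_level_probs[f.name] = {k: v / tot for k, v in sorted(c.items())}

    if schema.has_end_times:
        eh = np.zeros(24)
        ed = np.zeros(7)
        for rec in records:
            for v in rec.visits:
                if v.end_time is not None:
                    eh[v.end_time.hour] += 1
                    ed[v.end_time.weekday()] += 1
        if eh.sum():
            state.end_hour_probs = (eh / eh.sum()).tolist()
            state.end_dow_probs = (ed / ed.sum()).tolist()
    return state


def _choice(table: dict, rng) -> str:
    keys = list(table.keys())
    p = np.asarray(list(table.values()), float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def reconstruct_cohort(
    skeletons: list[PatientSkeleton],
    state: ReconstructionState,
    schema: CohortSchema,
    rng: np.random.Generator,
    stratify_by: str = "gender",
) -> list[PatientRecord]:
    """Rebuild continuous values, calendar timestamps and full codes."""
    cal = state.calendar
    records = []
    for sk in skeletons:
        rec = PatientRecord(sk.patient_id)
        # statics
        for f in schema.static_fields:
            if f.levels:
                lvl = sk.static_levels.get(f.name)
                if lvl is None and f.name in state.static_level_probs:
                    lvl = _choice(state.static_level_probs[f.name], rng)
                    state.flags["static_fallback"] += 1
                if lvl is not None:
                    rec.statics[f.name] = lvl
        gender = str(rec.statics.get(stratify_by, POOLED))
        for f in schema.static_fields:
            if f.kind == CONTINUOUS and f.name in sk.static_bands:
                band = f.band_bounds(sk.static_bands[f.name])
                rec.statics[f.name] = sample_within_band(
                    band, state.marginals[f.name], gender, rng
                )
        for lab, val in sk.labels.items():
            rec.statics[lab] = bool(val)

        # per-visit categorical values and the event type
        visits: list[Visit] = []
        for vs in sk.visits:
            v = Visit(start_time=None)
            for f in schema.categorical_visit_fields:
                lvl = vs.categoricals.get(f.name)
                if lvl is None and f.name in state.visit_level_probs:
                    lvl = _choice(state.visit_level_probs[f.name], rng)
                    state.flags["visit_cat_fallback"] += 1
                if lvl is not None:
                    v.categoricals[f.name] = lvl
            v.event_type = v.categoricals.get("event_type", vs.event_type)
            visits.append(v)

        # continuous values: joint pair first, then marginals
        for vs, v in zip(sk.visits, visits):
            et = str(v.event_type)
            if state.joint_pair is not None:
                nx, ny = state.joint_pair
                bx, by = vs.bands.get(nx), vs.bands.get(ny)
                if bx is not None and by is not None:
                    fx = schema.visit_field(nx)
                    fy = schema.visit_field(ny)
                    x, y = sample_joint_within_bands(
                        fx.band_bounds(bx), fy.band_bounds(by), state.joint,
                        rng, stratum=et,
                    )
                    v.continuous[nx], v.continuous[ny] = x, y
            for f in schema.continuous_visit_fields:
                if f.name in v.continuous or f.name not in vs.bands:
                    continue
                band = f.band_bounds(vs.bands[f.name])
                v.continuous[f.name] = sample_within_band(
                    band, state.marginals[f.name], (gender, et), rng
                )

        # inter-visit gap values (days) from gap bands
        gaps: list[float] = []
        gf = schema.gap_field
        for vs in sk.visits[1:]:
            b = vs.gap_band
            if b is None:
                if state.gap_band_probs:
                    b = int(rng.choice(len(state.gap_band_probs),
                                       p=state.gap_band_probs))
                    state.flags["gap_fallback"] += 1
                else:
                    b = 0
            gaps.append(sample_within_band(gf.band_bounds(b), state.gap_grid,
                                           POOLED, rng))

        # timestamps
        if schema.has_end_times:
            _date_admission_style(visits, gaps, state, cal, rng)
        else:
            gap_weeks = [0] + [max(0, int(round(g / 7.0))) for g in gaps]
            starts = reconstruct_visit_dates(gap_weeks, cal, rng)
            for v, s in zip(visits, starts):
                v.start_time = s

        # full-resolution codes (attached before any ordering repair so each
        # visit keeps its own diagnoses)
        for vs, v in zip(sk.visits, visits):
            for code in vs.codes:
                if state.aggregation is not None:
                    code = expand_codes(code, gender, state.aggregation, rng)
                v.codes.add(code)
        rec.visits = visits
        rec.sort_visits()  # overlap bands can invert start order
        records.append(rec)
    return records


def _date_admission_style(visits, gaps, state, cal, rng) -> None:
    """First admission from the start-week grid; discharges via the LOS
    tiers; subsequent admissions from the previous discharge plus the
    inter-visit interval."""
    if not visits:
        return
    start_week = cal.sample_start_week(len(visits), rng)
    d0 = cal.date_of(start_week, int(cal.sample_dow(rng)))
    t0 = datetime.combine(d0, datetime.min.time()) + timedelta(
        hours=int(cal.sample_hour(rng)), minutes=int(rng.integers(0, 60))
    )
    eh = np.asarray(state.end_hour_probs) if state.end_hour_probs else None
    ed = np.asarray(state.end_dow_probs) if state.end_dow_probs else None

    prev_anchor = None
    for i, v in enumerate(visits):
        if i == 0:
            v.start_time = t0
        else:
            interval_h = gaps[i - 1] * HOURS_PER_DAY
            timing = {"start_hour": int(cal.sample_hour(rng))}
            if interval_h > 7 * HOURS_PER_DAY:
                wk = cal.week_index(prev_anchor.date()) + int(
                    round(interval_h / (7 * HOURS_PER_DAY))
                )
                timing["event_week"] = wk
                timing["event_dow"] = int(cal.sample_dow(rng))
            v.start_time = derive_next_admission(prev_anchor, interval_h, timing, cal)
        los = v.continuous.get("total_los_hours")
        if los is not None:
            end_hour = int(rng.choice(24, p=eh)) if eh is not None else v.start_time.hour
            end_week = end_dow = None
            if los > 7 * HOURS_PER_DAY:
                end_week = cal.week_index(v.start_time.date()) + int(
                    round(los / (7 * HOURS_PER_DAY))
                )
                end_dow = int(rng.choice(7, p=ed)) if ed is not None else v.start_time.weekday()
            v.end_time = derive_discharge(v.start_time, los, end_hour,
                                          end_week, end_dow, cal)
        prev_anchor = v.end_time if v.end_time is not None else v.start_time
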