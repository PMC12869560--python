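"""Calendar timestamp reconstruction.

Start weeks are sampled from a KDE-derived probability grid stratified by
the patient's total visit count; each visit gets a day of week from the
empirical distribution, the cumulative event week is the start week plus
the summed inter-visit gaps, and (week, day) maps to a calendar date via a
lookup over the study window.  Admission/discharge times use a three-tier
logic driven by the length of stay (<= 24 h, 1–7 days, > 7 days), and
subsequent admissions mirror it using the inter-visit interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np

from .kde import KdeGrid, fit_marginal_kde

HOURS_PER_DAY = 24.0
TIER1_MAX_HOURS = 24.0       # "up to 24 hours" (inclusive)
TIER2_MAX_HOURS = 7 * 24.0   # "between 1 and 7 days" (inclusive)


def _monday_of(d: date) -> date:
    return d - timedelta(days=d.weekday())


@dataclass
class CalendarMaps:
    """Week-index lookup plus empirical timing distributions."""

    study_start: date
    study_end: date
    dow_probs: np.ndarray                      # Mon..Sun
    hour_probs: np.ndarray                     # 0..23
    start_week_grid: KdeGrid                   # stratified by total visit count
    visit_count_cap: int = 8
    clamp_count: int = 0

    def __post_init__(self):
        self.week0 = _monday_of(self.study_start)
        self.n_weeks = max(1, (self.study_end - self.week0).days // 7 + 1)

    # lookup table: bijective over the configured window
    def week_index(self, d: date) -> int:
        return (d - self.week0).days // 7

    def date_of(self, week: int, dow: int) -> date:
        w = int(week)
        if w < 0 or w >= self.n_weeks:
            self.clamp_count += 1
            w = min(max(w, 0), self.n_weeks - 1)
        return self.week0 + timedelta(days=7 * w + int(dow))

    def stratum_of(self, n_visits: int) -> str:
        return str(min(int(n_visits), self.visit_count_cap))

    def sample_start_week(self, n_visits: int, rng: np.random.Generator) -> int:
        sg = self.start_week_grid.stratum(self.stratum_of(n_visits))
        masses = sg.interval_masses()
        j = rng.choice(len(masses), p=masses)
        # grid points are week indices; take the interval's left week
        return int(round(sg.grid[j]))

    def sample_dow(self, rng, size=None):
        return rng.choice(7, p=self.dow_probs, size=size)

    def sample_hour(self, rng, size=None):
        return rng.choice(24, p=self.hour_probs, size=size)

    def to_dict(self) -> dict:
        return {
            "study_start": self.study_start.isoformat(),
            "study_end": self.study_end.isoformat(),
            "dow_probs": self.dow_probs.tolist(),
            "hour_probs": self.hour_probs.tolist(),
            "start_week_grid": self.start_week_grid.to_dict(),
            "visit_count_cap": self.visit_count_cap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalendarMaps":
        return cls(
            study_start=date.fromisoformat(d["study_start"]),
            study_end=date.fromisoformat(d["study_end"]),
            dow_probs=np.asarray(d["dow_probs"]),
            hour_probs=np.asarray(d["hour_probs"]),
            start_week_grid=KdeGrid.from_dict(d["start_week_grid"]),
            visit_count_cap=d["visit_count_cap"],
        )


def fit_calendar_maps(records, schema, visit_count_cap: int = 8,
                      min_stratum_n: int = 30) -> CalendarMaps:
    """Empirical day-of-week/hour tables and visit-count-stratified
    start-week grids from training records."""
    dow = np.zeros(7)
    hour = np.zeros(24)
    first_weeks, strata = [], []
    week0 = _monday_of(schema.study_start)
    for rec in records:
        if not rec.visits:
            continue
        for v in rec.visits:
            if v.start_time is None:
                continue
            dow[v.start_time.weekday()] += 1
            hour[v.start_time.hour] += 1
        first = rec.visits[0].start_time
        if first is not None:
            first_weeks.append((first.date() - week0).days // 7)
            strata.append(str(min(len(rec.visits), visit_count_cap)))
    if dow.sum() == 0:
        raise ValueError("no dated visits to fit calendar maps")
    grid = fit_marginal_kde(
        np.asarray(first_weeks, float), strata, grid_resolution=1.0,
        min_stratum_n=min_stratum_n, variable="start_week",
    )
    return CalendarMaps(
        study_start=schema.study_start,
        study_end=schema.study_end,
        dow_probs=dow / dow.sum(),
        hour_probs=hour / hour.sum(),
        start_week_grid=grid,
        visit_count_cap=visit_count_cap,
    )


def reconstruct_visit_dates(gap_weeks: Sequence[int], calendar_maps: CalendarMaps,
                            rng: np.random.Generator,
                            start_week: Optional[int] = None) -> list[datetime]:
    """Date each visit of one patient from its gap-week values.

    ``gap_weeks`` holds one entry per visit — the interval in whole weeks
    since the previous visit, with 0 for the first visit; visit weeks are
    the cumulative sum added to the sampled start week.
    """
    k = len(gap_weeks)
    if start_week is None:
        start_week = calendar_maps.sample_start_week(k, rng)
    weeks = start_week + np.cumsum(np.asarray(gap_weeks, int))
    out = []
    for w in weeks:
        d = calendar_maps.date_of(w, int(calendar_maps.sample_dow(rng)))
        h = int(calendar_maps.sample_hour(rng))
        out.append(datetime.combine(d, time(hour=h, minute=int(rng.integers(0, 60)))))
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def derive_discharge(admission_time: datetime, los_hours: float,
                     end_hour: int, end_week: Optional[int],
                     end_dow: Optional[int],
                     calendar_maps: CalendarMaps) -> datetime:
    """Three-tier discharge: exact for short stays, day-resolution with a
    synthetic end hour for 1–7 day stays, week lookup beyond."""
    if los_hours < 0:
        raise ValueError("length of stay must be nonnegative")
    if los_hours <= TIER1_MAX_HOURS:
        return admission_time + timedelta(hours=float(los_hours))
    if los_hours <= TIER2_MAX_HOURS:
        days = max(1, _round_half_up(los_hours / HOURS_PER_DAY))
        out = datetime.combine(
            admission_time.date() + timedelta(days=days), time(hour=int(end_hour))
        )
        return max(out, admission_time)
    if end_week is None or end_dow is None:
        # fall back to day arithmetic when no event-timing features exist
        days = max(1, _round_half_up(los_hours / HOURS_PER_DAY))
        out = datetime.combine(
            admission_time.date() + timedelta(days=days), time(hour=int(end_hour))
        )
        return max(out, admission_time)
    d = calendar_maps.date_of(int(end_week), int(end_dow))
    out = datetime.combine(d, time(hour=int(end_hour)))
    return max(out, admission_time)


def derive_next_admission(prev_discharge: datetime, interval_hours: float,
                          event_timing: dict,
                          calendar_maps: CalendarMaps) -> datetime:
    """Next admission from the previous discharge and inter-visit interval.

    Mirrors the discharge tiers; a negative interval (overlap band) places
    the admission before the previous discharge, and callers restore start
    ordering by a stable post-sort.  ``event_timing`` may carry
    ``start_hour``, ``event_week`` and ``event_dow``.
    """
    start_hour = event_timing.get("start_hour")
    if interval_hours <= TIER1_MAX_HOURS:
        return prev_discharge + timedelta(hours=float(interval_hours))
    if interval_hours <= TIER2_MAX_HOURS:
        days = max(1, _round_half_up(interval_hours / HOURS_PER_DAY))
        h = int(start_hour) if start_hour is not None else prev_discharge.hour
        return datetime.combine(
            prev_discharge.date() + timedelta(days=days), time(hour=h)
        )
    week = event_timing.get("event_week")
    dow = event_timing.get("event_dow")
    h = int(start_hour) if start_hour is not None else prev_discharge.hour
    if week is None or dow is None:
        days = max(1, _round_half_up(interval_hours / HOURS_PER_DAY))
        return datetime.combine(
            prev_discharge.date() + timedelta(days=days), time(hour=h)
        )
    d = calendar_maps.date_of(int(week), int(dow))
    return datetime.combine(d, time(hour=h))
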