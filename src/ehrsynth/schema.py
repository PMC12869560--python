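"""Declarative cohort schemas.

A :class:`CohortSchema` describes the three-table layout of a longitudinal
cohort — static patient fields, per-visit fields (with band definitions for
continuous variables), one or more diagnosis-code systems, the inter-visit
gap variable and the visit cap — and is the single source of truth for
tokenization, reconstruction and evaluation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Optional, Sequence

import numpy as np
import yaml

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"
BINARY_LABEL = "binary_label"

_KINDS = (CATEGORICAL, CONTINUOUS, BINARY_LABEL)


class SchemaError(ValueError):
    """Raised when a schema (or data inconsistent with it) is invalid."""


@dataclass
class FieldSpec:
    """One static or visit-level field.

    For continuous fields either explicit ``band_edges`` (strictly
    increasing, tiling the declared range) or an ``n_bands`` count may be
    given; in the latter case edges are derived from training data with
    :func:`resolve_bands`.
    """

    name: str
    kind: str
    levels: Optional[list[str]] = None       # categorical
    band_edges: Optional[list[float]] = None  # continuous
    n_bands: int = 20

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SchemaError(f"unknown field kind {self.kind!r} for {self.name!r}")
        if self.kind == CATEGORICAL and not self.levels:
            raise SchemaError(f"categorical field {self.name!r} needs levels")
        if self.band_edges is not None:
            edges = np.asarray(self.band_edges, dtype=float)
            if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
                raise SchemaError(
                    f"band_edges for {self.name!r} must be strictly increasing "
                    f"with at least two entries"
                )

    @property
    def n_defined_bands(self) -> int:
        if self.band_edges is None:
            raise SchemaError(f"bands for {self.name!r} not resolved yet")
        return len(self.band_edges) - 1

    def band_of(self, value: float) -> tuple[int, bool]:
        """Band index for ``value``; second element flags an out-of-range clamp.

        Bands are half-open ``[e_i, e_{i+1})`` with the last band closed on
        the right.
        """
        edges = np.asarray(self.band_edges, dtype=float)
        clamped = False
        if value < edges[0]:
            return 0, True
        if value > edges[-1]:
            return len(edges) - 2, True
        idx = int(np.searchsorted(edges, value, side="right") - 1)
        idx = min(idx, len(edges) - 2)
        return idx, clamped

    def band_bounds(self, band: int) -> tuple[float, float]:
        return float(self.band_edges[band]), float(self.band_edges[band + 1])


@dataclass
class CodeSystemSpec:
    name: str
    vocabulary: list[str]

    def __post_init__(self) -> None:
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise SchemaError(f"code system {self.name!r} has duplicate codes")


@dataclass
class CohortSchema:
    static_fields: list[FieldSpec]
    visit_fields: list[FieldSpec]
    code_systems: list[CodeSystemSpec]
    gap_field: FieldSpec
    max_visits: int
    event_types: list[str]
    has_end_times: bool = True
    study_start: date = date(2018, 1, 1)
    study_end: date = date(2020, 12, 31)

    def __post_init__(self) -> None:
        if self.max_visits < 1:
            raise SchemaError("max_visits must be >= 1")
        if self.gap_field.kind != CONTINUOUS:
            raise SchemaError("gap_field must be continuous")
        names = [f.name for f in self.static_fields + self.visit_fields] + [
            self.gap_field.name
        ]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate field names in schema")
        if isinstance(self.study_start, str):
            self.study_start = date.fromisoformat(self.study_start)
        if isinstance(self.study_end, str):
            self.study_end = date.fromisoformat(self.study_end)

    # -- lookups -----------------------------------------------------------
    def static(self, name: str) -> FieldSpec:
        for f in self.static_fields:
            if f.name == name:
                return f
        raise SchemaError(f"no static field {name!r}")

    def visit_field(self, name: str) -> FieldSpec:
        for f in self.visit_fields:
            if f.name == name:
                return f
        raise SchemaError(f"no visit field {name!r}")

    @property
    def continuous_visit_fields(self) -> list[FieldSpec]:
        return [f for f in self.visit_fields if f.kind == CONTINUOUS]

    @property
    def categorical_visit_fields(self) -> list[FieldSpec]:
        return [f for f in self.visit_fields if f.kind == CATEGORICAL]

    def code_system(self, name: str) -> CodeSystemSpec:
        for cs in self.code_systems:
            if cs.name == name:
                return cs
        raise SchemaError(f"no code system {name!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSchema":
        return cls(
            static_fields=[FieldSpec(**f) for f in d["static_fields"]],
            visit_fields=[FieldSpec(**f) for f in d["visit_fields"]],
            code_systems=[CodeSystemSpec(**c) for c in d["code_systems"]],
            gap_field=FieldSpec(**d["gap_field"]),
            max_visits=d["max_visits"],
            event_types=list(d["event_types"]),
            has_end_times=d.get("has_end_times", True),
            study_start=d.get("study_start", "2018-01-01"),
            study_end=d.get("study_end", "2020-12-31"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def quantile_band_edges(values: Sequence[float], n_bands: int) -> list[float]:
    """Quantile band edges bounding per-band mass, deduplicated for ties."""
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)], float)
    if v.size == 0:
        raise SchemaError("cannot derive bands from empty data")
    qs = np.quantile(v, np.linspace(0, 1, n_bands + 1))
    edges = np.unique(qs)
    if len(edges) < 2:
        edges = np.array([edges[0], edges[0] + 1.0])
    # widen the last edge slightly so the max value falls inside
    edges = edges.astype(float)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    return edges.tolist()


def hybrid_gap_edges(max_days: float, negative: bool = True) -> list[float]:
    """Gap-band grid: per-day up to 7 days, per-week beyond.

    A dedicated negative/overlap band ``[-2, 0)`` captures admissions that
    begin before the previous discharge.
    """
    edges: list[float] = [-2.0] if negative else []
    edges += [float(d) for d in range(0, 8)]  # 0..7 daily
    wk = 14.0
    while wk <= max_days + 7.0:
        edges.append(wk)
        wk += 7.0
    return edges


def resolve_bands(schema: CohortSchema, records) -> CohortSchema:
    """Fill in missing band edges from training data (quantile bands).

    The gap field, when unresolved, receives the hybrid day/week grid so the
    bands line up with the timestamp-reconstruction tiers.
    """
    from .cohort import iter_field_values, iter_gap_values  # local import

    schema = dataclasses.replace(
        schema,
        static_fields=[dataclasses.replace(f) for f in schema.static_fields],
        visit_fields=[dataclasses.replace(f) for f in schema.visit_fields],
        gap_field=dataclasses.replace(schema.gap_field),
    )
    for f in schema.static_fields + schema.visit_fields:
        if f.kind == CONTINUOUS and f.band_edges is None:
            f.band_edges = quantile_band_edges(
                iter_field_values(records, f.name), f.n_bands
            )
    if schema.gap_field.band_edges is None:
        gaps = list(iter_gap_values(records, schema))
        max_gap = max(gaps) if gaps else 28.0
        neg = (min(gaps) < 0) if gaps else schema.has_end_times
        schema.gap_field.band_edges = hybrid_gap_edges(max_gap, negative=neg)
    return schema
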