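"""Hierarchical longitudinal records: patients with ordered visit lists."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional


@dataclass
class Visit:
    """One encounter: timestamps, event type, codes and visit-level values.

    ``continuous`` holds real values (length-of-stay in hours, gaps in
    days); a missing value is simply absent from the map — missingness is
    informative and is preserved end to end.
    """

    start_time: Optional[datetime]
    end_time: Optional[datetime] = None
    event_type: Optional[str] = None
    codes: set[str] = field(default_factory=set)
    categoricals: dict[str, str] = field(default_factory=dict)
    continuous: dict[str, float] = field(default_factory=dict)


@dataclass
class PatientRecord:
    patient_id: str
    statics: dict[str, object] = field(default_factory=dict)
    visits: list[Visit] = field(default_factory=list)

    def sort_visits(self) -> None:
        self.visits.sort(key=lambda v: (v.start_time is None, v.start_time))


# --- skeletons: banded records awaiting reconstruction --------------------


@dataclass
class VisitSkeleton:
    """A visit whose continuous fields are still band indices.

    ``bands[name]`` is the band index of a discretized variable (absent =>
    missing); ``gap_band`` is the inter-visit interval band (None for the
    first visit or when the generator omitted it).
    """

    event_type: Optional[str] = None
    codes: set[str] = field(default_factory=set)
    categoricals: dict[str, str] = field(default_factory=dict)
    bands: dict[str, int] = field(default_factory=dict)
    gap_band: Optional[int] = None


@dataclass
class PatientSkeleton:
    patient_id: str
    static_levels: dict[str, str] = field(default_factory=dict)
    static_bands: dict[str, int] = field(default_factory=dict)
    labels: dict[str, bool] = field(default_factory=dict)
    visits: list[VisitSkeleton] = field(default_factory=list)
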