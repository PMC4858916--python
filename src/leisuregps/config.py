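"""Study configuration: epoch grid, pipeline thresholds, school schedules, geofences.

Every numeric constant of the processing chain lives in :class:`Thresholds` so
that each rule (speed bands, trip minimum, pause allowance, wear criteria) is
inspectable and overridable from the CLI or a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import time
from pathlib import Path
from typing import Mapping

import yaml

WEEKDAY_NAMES = ["monday", "tuesday", "wednesday", "thursday", "friday"]


@dataclass
class Thresholds:
    """All numeric constants of the trip/wear pipeline.

    Speed bands follow the trip-mode classification used for children's
    travel: walking 1 to <10 km/h, cycling 10 to <25 km/h, passive (vehicle)
    >=25 km/h; below 1 km/h an epoch is stationary.
    """

    movement_kmh: float = 1.0          # below this an epoch is stationary
    walk_max_kmh: float = 10.0         # walk band: [movement_kmh, walk_max_kmh)
    cycle_max_kmh: float = 25.0        # cycle band: [walk_max_kmh, cycle_max_kmh); passive >= cycle_max_kmh
    min_trip_min: float = 3.0          # minimum total trip duration
    max_pause_min: float = 5.0         # stationary allowance inside a trip
    split_persistence_epochs: int = 4  # moving epochs in a new band needed to split a trip
    smooth_window: int = 5             # running-median window (epochs); 1 disables
    nonwear_min: float = 60.0          # zero-count run length counting as non-wear
    min_wear_hours: float = 9.0        # combined (accel wear AND GPS fix) hours for a valid day
    min_valid_days: int = 4
    min_weekend_days: int = 1
    geofence_m: float = 100.0          # home/school anchor radius

    def __post_init__(self) -> None:
        if not (0 < self.movement_kmh < self.walk_max_kmh < self.cycle_max_kmh):
            raise ValueError("mode band edges must be strictly increasing and positive")
        for name in ("min_trip_min", "max_pause_min", "nonwear_min", "min_wear_hours", "geofence_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _parse_time(v) -> time:
    if isinstance(v, time):
        return v
    h, m = str(v).split(":")[:2]
    return time(int(h), int(m))


@dataclass
class SchoolSchedule:
    """Per-weekday school start/end clock times (Wednesday may end earlier)."""

    school_id: str
    hours: Mapping[str, tuple[time, time]]  # weekday name -> (start, end)

    def __post_init__(self) -> None:
        fixed = {}
        for day, (start, end) in dict(self.hours).items():
            start, end = _parse_time(start), _parse_time(end)
            if day not in WEEKDAY_NAMES:
                raise ValueError(f"unknown weekday {day!r}")
            if start >= end:
                raise ValueError(f"school start must precede end on {day}")
            fixed[day] = (start, end)
        self.hours = fixed

    @classmethod
    def regular(cls, school_id: str, start: str = "08:30", end: str = "15:45",
                wednesday_end: str = "12:00") -> "SchoolSchedule":
        """Belgian-style week: Mon–Fri with an early Wednesday close."""
        hours = {d: (start, end) for d in WEEKDAY_NAMES}
        hours["wednesday"] = (start, wednesday_end)
        return cls(school_id, hours)

    def for_date(self, date) -> tuple[time, time] | None:
        """School hours on a calendar date, or None on non-school days."""
        wd = date.weekday()
        if wd >= 5:
            return None
        return self.hours.get(WEEKDAY_NAMES[wd])


@dataclass
class GeoAnchor:
    """A labelled geofenced location (home or school)."""

    label: str
    lat: float
    lon: float
    radius_m: float = 100.0

    def __post_init__(self) -> None:
        if self.label not in ("home", "school"):
            raise ValueError("anchor label must be 'home' or 'school'")
        if self.radius_m <= 0:
            raise ValueError("radius_m must be positive")
        if abs(self.lat) > 90 or abs(self.lon) > 180:
            raise ValueError("anchor coordinates out of range")


@dataclass
class StudyConfig:
    """Everything the pipeline needs besides the raw data streams."""

    epoch_s: int = 15
    thresholds: Thresholds = field(default_factory=Thresholds)
    schools: dict[str, SchoolSchedule] = field(default_factory=dict)
    participant_school: dict[str, str] = field(default_factory=dict)
    anchors: dict[str, dict[str, GeoAnchor]] = field(default_factory=dict)  # pid -> {home, school}

    def school_for(self, participant_id: str) -> SchoolSchedule:
        return self.schools[self.participant_school[participant_id]]

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "epoch_s": self.epoch_s,
            "thresholds": asdict(self.thresholds),
            "schools": {
                sid: {d: [s.strftime("%H:%M"), e.strftime("%H:%M")] for d, (s, e) in sch.hours.items()}
                for sid, sch in self.schools.items()
            },
            "participant_school": dict(self.participant_school),
            "anchors": {
                pid: {lbl: {"lat": a.lat, "lon": a.lon, "radius_m": a.radius_m} for lbl, a in d.items()}
                for pid, d in self.anchors.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        return cls(
            epoch_s=int(d.get("epoch_s", 15)),
            thresholds=Thresholds(**d.get("thresholds", {})),
            schools={
                sid: SchoolSchedule(sid, {day: tuple(v) for day, v in hrs.items()})
                for sid, hrs in d.get("schools", {}).items()
            },
            participant_school=dict(d.get("participant_school", {})),
            anchors={
                pid: {lbl: GeoAnchor(lbl, **a) for lbl, a in locs.items()}
                for pid, locs in d.get("anchors", {}).items()
            },
        )

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
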