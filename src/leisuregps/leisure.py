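"""Leisure-time restriction, school-commute exclusion, and outcome variables.

Leisure time is all time outside school hours on weekdays plus entire
weekend days; trips between the home and school geofences are excluded
unconditionally (weekends included). Outcomes are per-participant means
over valid days, stratified week/weekend: trips/day, minutes/day and
minutes/trip per transport mode, plus an engagement flag.
"""

from __future__ import annotations

import logging
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

from .config import GeoAnchor, SchoolSchedule, StudyConfig
from .trips import Trip, trips_to_frame
from .util import haversine_m

logger = logging.getLogger(__name__)

MODES = ["walk", "cycle", "passive"]
STRATA = ["week", "weekend"]

OUTCOME_COLUMNS = [
    "participant_id", "stratum", "mode",
    "trips_per_day", "minutes_per_day", "minutes_per_trip", "engaged",
]


def leisure_window(date, school: SchoolSchedule | None) -> list[tuple[datetime, datetime]]:
    """Leisure intervals on a calendar date: full weekend days, before/after
    school on school days (Wednesday afternoons are leisure after the early
    close)."""
    date = pd.Timestamp(date).date()
    day0 = datetime.combine(date, time(0, 0))
    day1 = day0 + timedelta(days=1)
    hours = school.for_date(date) if school is not None else None
    if hours is None:
        return [(day0, day1)]
    start, end = (datetime.combine(date, h) for h in hours)
    return [(day0, start), (end, day1)]


def in_leisure_window(when: datetime, school: SchoolSchedule | None) -> bool:
    return any(a <= when < b for a, b in leisure_window(when.date(), school))


def is_school_trip(trip: Trip, anchors: dict[str, GeoAnchor]) -> bool:
    """True iff one trip endpoint is inside the home geofence and the other
    inside the school geofence (either direction)."""
    if "home" not in anchors or "school" not in anchors:
        raise ValueError(f"missing home/school anchors for {trip.participant_id}")
    home, school = anchors["home"], anchors["school"]
    if any(np.isnan(v) for v in (trip.start_lat, trip.start_lon, trip.end_lat, trip.end_lon)):
        return False

    def near(lat, lon, anchor):
        return haversine_m(lat, lon, anchor.lat, anchor.lon) <= anchor.radius_m

    start_home = near(trip.start_lat, trip.start_lon, home)
    start_school = near(trip.start_lat, trip.start_lon, school)
    end_home = near(trip.end_lat, trip.end_lon, home)
    end_school = near(trip.end_lat, trip.end_lon, school)
    return bool((start_home and end_school) or (start_school and end_home))


def filter_leisure_trips(trips: list[Trip], weardays: pd.DataFrame,
                         config: StudyConfig) -> list[Trip]:
    """Keep trips on valid days whose temporal midpoint is in the leisure
    window and which are not home<->school commutes."""
    valid = {
        (r.participant_id, pd.Timestamp(r.date).date())
        for r in weardays.itertuples(index=False) if r.is_valid
    }
    kept = []
    for trip in trips:
        mid = trip.midpoint.to_pydatetime()
        if (trip.participant_id, mid.date()) not in valid:
            continue
        school = (config.schools.get(config.participant_school.get(trip.participant_id))
                  if config.participant_school else None)
        if not in_leisure_window(mid, school):
            continue
        anchors = config.anchors.get(trip.participant_id)
        if anchors and is_school_trip(trip, anchors):
            continue
        kept.append(trip)
    return kept


def _valid_day_counts(weardays: pd.DataFrame) -> pd.DataFrame:
    wd = weardays[weardays["is_valid"]].copy()
    wd["stratum"] = np.where(wd["is_weekend"], "weekend", "week")
    return wd.groupby(["participant_id", "stratum"], observed=True).size().rename("valid_days").reset_index()


def aggregate_trip_table(trip_table: pd.DataFrame, weardays: pd.DataFrame,
                         participants=None) -> pd.DataFrame:
    """Aggregate a (participant_id, date, mode, duration_min) trip table into
    the per-participant x stratum x mode outcome table.

    Averages use valid days only. ``participants`` restricts/expands the
    participant set (e.g. the inclusion list); participants without a valid
    day in a stratum get undefined (NaN) outcomes and are logged.
    """
    denom = _valid_day_counts(weardays)
    if participants is None:
        participants = sorted(denom["participant_id"].unique())
    grid = pd.MultiIndex.from_product(
        [participants, STRATA, MODES], names=["participant_id", "stratum", "mode"]
    ).to_frame(index=False)
    if trip_table.empty:
        agg = pd.DataFrame(columns=["participant_id", "stratum", "mode", "n_trips", "total_min"])
    else:
        tt = trip_table.copy()
        tt["stratum"] = np.where(pd.to_datetime(tt["date"]).dt.weekday >= 5, "weekend", "week")
        agg = (
            tt.groupby(["participant_id", "stratum", "mode"], observed=True)
            .agg(n_trips=("mode", "size"), total_min=("duration_min", "sum"))
            .reset_index()
        )
    out = grid.merge(agg, how="left").merge(denom, how="left")
    out[["n_trips", "total_min"]] = out[["n_trips", "total_min"]].fillna(0.0)
    no_days = out["valid_days"].isna() | (out["valid_days"] == 0)
    if no_days.any():
        for pid, stratum in out.loc[no_days, ["participant_id", "stratum"]].drop_duplicates().itertuples(index=False):
            logger.warning("participant %s has no valid %s days; outcomes undefined", pid, stratum)
    out["trips_per_day"] = out["n_trips"] / out["valid_days"]
    out["minutes_per_day"] = out["total_min"] / out["valid_days"]
    out["minutes_per_trip"] = np.where(out["n_trips"] > 0, out["total_min"] / out["n_trips"], np.nan)
    out["engaged"] = (out["n_trips"] > 0) & ~no_days
    return out[OUTCOME_COLUMNS + ["valid_days"]]


def compute_outcomes(leisure_trips: list[Trip], weardays: pd.DataFrame,
                     inclusion: pd.DataFrame | None = None) -> pd.DataFrame:
    """GPS outcome table from detected leisure trips (valid-day means)."""
    tf = trips_to_frame(leisure_trips)
    table = pd.DataFrame({
        "participant_id": tf["participant_id"],
        "date": pd.to_datetime(tf["start"]) + (pd.to_datetime(tf["end"]) - pd.to_datetime(tf["start"])) / 2,
        "mode": tf["mode"],
        "duration_min": tf["duration_min"],
    })
    table["date"] = table["date"].dt.date
    participants = None
    if inclusion is not None:
        participants = sorted(inclusion.loc[inclusion["included"], "participant_id"])
        table = table[table["participant_id"].isin(participants)]
    return aggregate_trip_table(table, weardays, participants)


def diary_outcomes(diary: pd.DataFrame, weardays: pd.DataFrame,
                   inclusion: pd.DataFrame | None = None) -> pd.DataFrame:
    """Self-reported trips/day per mode x stratum, using the same valid-day
    denominators as the GPS outcomes (school trips excluded; diary carries
    no durations, so minutes columns are NaN)."""
    d = diary[~diary["is_school_trip"]].copy()
    valid = {(r.participant_id, pd.Timestamp(r.date).date())
             for r in weardays.itertuples(index=False) if r.is_valid}
    d = d[[(r.participant_id, pd.Timestamp(r.date).date()) in valid
           for r in d.itertuples(index=False)]]
    d["duration_min"] = np.nan
    participants = None
    if inclusion is not None:
        participants = sorted(inclusion.loc[inclusion["included"], "participant_id"])
        d = d[d["participant_id"].isin(participants)]
    out = aggregate_trip_table(
        d[["participant_id", "date", "mode", "duration_min"]], weardays, participants
    )
    out[["minutes_per_day", "minutes_per_trip"]] = np.nan
    return out
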