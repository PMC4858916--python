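"""Leisure windows, school-trip geofencing, outcome aggregation."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from leisuregps.config import GeoAnchor, SchoolSchedule, StudyConfig
from leisuregps.leisure import (
    aggregate_trip_table, compute_outcomes, filter_leisure_trips, is_school_trip,
    leisure_window,
)
from leisuregps.preprocess import flag_valid_days, include_participants
from leisuregps.trips import Trip, detect_trips
from leisuregps.util import offset_latlon

SCHED = SchoolSchedule.regular("S1", start="08:30", end="16:00", wednesday_end="12:00")


class TestLeisureWindow:
    def test_saturday_is_fully_leisure(self):
        w = leisure_window("2014-01-11", SCHED)  # Saturday
        assert w == [(datetime(2014, 1, 11, 0, 0), datetime(2014, 1, 12, 0, 0))]

    def test_school_day_splits_around_hours(self):
        w = leisure_window("2014-01-06", SCHED)  # Monday
        assert w[0][1] == datetime(2014, 1, 6, 8, 30)
        assert w[1][0] == datetime(2014, 1, 6, 16, 0)

    def test_wednesday_afternoon_is_leisure(self):
        w = leisure_window("2014-01-08", SCHED)  # Wednesday, early close
        assert w[1][0] == datetime(2014, 1, 8, 12, 0)


HOME = GeoAnchor("home", 51.0, 3.70, 100.0)
SCHOOL_LAT, SCHOOL_LON = offset_latlon(51.0, 3.70, 800.0, 0.0)
SCHOOL = GeoAnchor("school", float(SCHOOL_LAT), float(SCHOOL_LON), 100.0)
ANCHORS = {"home": HOME, "school": SCHOOL}


def make_trip(start="2014-01-06 17:00:00", dur_min=10.0, mode="walk",
              a=(HOME.lat, HOME.lon), b=(SCHOOL.lat, SCHOOL.lon), pid="P1"):
    start = pd.Timestamp(start)
    return Trip(participant_id=pid, start=start,
                end=start + pd.Timedelta(minutes=dur_min), mode=mode,
                duration_min=dur_min, median_speed_kmh=5.0,
                start_lat=a[0], start_lon=a[1], end_lat=b[0], end_lon=b[1])


class TestSchoolTrip:
    def test_home_to_school_flagged(self):
        assert is_school_trip(make_trip(), ANCHORS)

    def test_school_to_home_flagged(self):
        t = make_trip(a=(SCHOOL.lat, SCHOOL.lon), b=(HOME.lat, HOME.lon))
        assert is_school_trip(t, ANCHORS)

    def test_home_to_shop_not_flagged(self):
        shop = offset_latlon(51.0, 3.70, -900.0, 300.0)
        t = make_trip(b=(float(shop[0]), float(shop[1])))
        assert not is_school_trip(t, ANCHORS)

    def test_missing_anchor_is_error(self):
        with pytest.raises(ValueError):
            is_school_trip(make_trip(), {"home": HOME})

    def test_weekend_commute_still_flagged_and_excluded(self):
        # "all trips to and from school" is unconditional, weekends included
        wd = pd.DataFrame([{"participant_id": "P1", "date": pd.Timestamp("2014-01-11").date(),
                            "is_valid": True, "is_weekend": True,
                            "combined_wear_minutes": 600, "is_first_day": False}])
        cfg = StudyConfig(schools={"S1": SCHED}, participant_school={"P1": "S1"},
                          anchors={"P1": ANCHORS})
        t = make_trip(start="2014-01-11 10:00:00")  # Saturday home->school
        assert is_school_trip(t, ANCHORS)
        assert filter_leisure_trips([t], wd, cfg) == []


class TestFilter:
    CFG = StudyConfig(schools={"S1": SCHED}, participant_school={"P1": "S1"},
                      anchors={"P1": ANCHORS})
    WD = pd.DataFrame([
        {"participant_id": "P1", "date": pd.Timestamp("2014-01-08").date(),  # Wed
         "is_valid": True, "is_weekend": False, "combined_wear_minutes": 600,
         "is_first_day": False},
        {"participant_id": "P1", "date": pd.Timestamp("2014-01-06").date(),  # Mon
         "is_valid": True, "is_weekend": False, "combined_wear_minutes": 600,
         "is_first_day": False},
    ])

    def test_wednesday_lunchtime_trip_kept(self):
        shop = offset_latlon(51.0, 3.70, -900.0, 0.0)
        t = make_trip(start="2014-01-08 12:10:00", b=(float(shop[0]), float(shop[1])))
        assert filter_leisure_trips([t], self.WD, self.CFG) == [t]

    def test_morning_commute_dropped(self):
        t = make_trip(start="2014-01-06 08:00:00")
        assert filter_leisure_trips([t], self.WD, self.CFG) == []

    def test_invalid_day_trip_dropped(self):
        shop = offset_latlon(51.0, 3.70, -900.0, 0.0)
        t = make_trip(start="2014-01-07 17:00:00", b=(float(shop[0]), float(shop[1])))
        assert filter_leisure_trips([t], self.WD, self.CFG) == []

    def test_midpoint_decides_boundary_straddlers(self):
        # trip 15:55-16:10 on Monday: midpoint 16:02:30 is after school -> kept
        shop = offset_latlon(51.0, 3.70, -900.0, 0.0)
        t = make_trip(start="2014-01-06 15:55:00", dur_min=15.0,
                      b=(float(shop[0]), float(shop[1])))
        assert filter_leisure_trips([t], self.WD, self.CFG) == [t]


class TestOutcomes:
    def test_trips_per_day_uses_valid_day_denominator(self):
        # 8 walk trips over 4 valid weekdays -> 2.0 trips/day
        dates = [pd.Timestamp(f"2014-01-{d:02d}").date() for d in (7, 8, 9, 10)]
        wd = pd.DataFrame([{"participant_id": "P1", "date": d, "is_valid": True,
                            "is_weekend": False, "combined_wear_minutes": 600,
                            "is_first_day": False} for d in dates])
        tt = pd.DataFrame({
            "participant_id": "P1",
            "date": [dates[i % 4] for i in range(8)],
            "mode": "walk", "duration_min": 6.0,
        })
        out = aggregate_trip_table(tt, wd)
        row = out[(out["mode"] == "walk") & (out["stratum"] == "week")].iloc[0]
        assert row["trips_per_day"] == pytest.approx(2.0)
        assert row["minutes_per_day"] == pytest.approx(12.0)
        assert row["minutes_per_trip"] == pytest.approx(6.0)
        zero = out[(out["mode"] == "cycle") & (out["stratum"] == "week")].iloc[0]
        assert not zero["engaged"] and zero["trips_per_day"] == 0.0

    def test_minutes_identity_links_the_three_measures(self):
        rng = np.random.default_rng(8)
        dates = pd.date_range("2014-01-06", periods=7)
        wd = pd.DataFrame([{"participant_id": "P1", "date": d.date(), "is_valid": i > 0,
                            "is_weekend": d.weekday() >= 5, "combined_wear_minutes": 600,
                            "is_first_day": i == 0} for i, d in enumerate(dates)])
        tt = pd.DataFrame({
            "participant_id": "P1",
            "date": rng.choice(dates[1:].date, 20),
            "mode": rng.choice(["walk", "cycle", "passive"], 20),
            "duration_min": rng.uniform(3, 15, 20),
        })
        out = aggregate_trip_table(tt, wd)
        pos = out[out["engaged"]]
        implied = pos["minutes_per_day"] * pos["valid_days"] / (pos["trips_per_day"] * pos["valid_days"])
        assert np.allclose(implied, pos["minutes_per_trip"])
        # total minutes per stratum below a day length
        assert (out.groupby(["participant_id", "stratum"])["minutes_per_day"].sum() <= 1440).all()

    def test_noise_free_outcomes_match_manifest(self, noise_free_study):
        study = noise_free_study
        cfg = study.study_config
        wd = flag_valid_days(study.epochs, cfg)
        inc = include_participants(wd, cfg)
        trips = detect_trips(study.epochs, cfg)
        leis = filter_leisure_trips(trips, wd, cfg)
        got = compute_outcomes(leis, wd, inc)
        expected = study.manifest.expected_outcomes()
        m = got.merge(expected, on=["participant_id", "stratum", "mode"],
                      suffixes=("", "_exp"))
        assert len(m) == len(expected)
        assert np.allclose(m["trips_per_day"], m["trips_per_day_exp"], atol=1e-9)
        # minutes within one epoch per trip per day
        assert (np.abs(m["minutes_per_day"] - m["minutes_per_day_exp"])
                <= 0.25 * np.maximum(m["trips_per_day"], 1)).all()

    def test_every_trip_classified_into_exactly_one_bucket(self, noise_free_study):
        """Partition: leisure + school-commute + in-school-hours covers all
        trips on valid days, and only leisure trips feed outcomes."""
        study = noise_free_study
        cfg = study.study_config
        wd = flag_valid_days(study.epochs, cfg)
        valid = {(r.participant_id, pd.Timestamp(r.date).date())
                 for r in wd.itertuples() if r.is_valid}
        trips = [t for t in detect_trips(study.epochs, cfg)
                 if (t.participant_id, t.midpoint.date()) in valid]
        leis = set(id(t) for t in filter_leisure_trips(trips, wd, cfg))
        from leisuregps.leisure import in_leisure_window, is_school_trip as ist
        n_school = n_inschool = 0
        for t in trips:
            school = cfg.schools[cfg.participant_school[t.participant_id]]
            buckets = [id(t) in leis,
                       ist(t, cfg.anchors[t.participant_id]),
                       not in_leisure_window(t.midpoint.to_pydatetime(), school)]
            assert sum(1 for b in buckets if b) >= 1
            assert (id(t) in leis) == (not buckets[1] and not buckets[2])
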