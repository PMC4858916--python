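"""Trip engine: speed banding, smoothing, segmentation, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from leisuregps.config import StudyConfig
from leisuregps.trips import classify_epoch_speed, detect_trips, smooth_speeds, trips_to_frame

from conftest import epochs_frame
from reference import ref_trips, random_speed_stream

CFG = StudyConfig()
MODE_CODE = {"walk": 1, "cycle": 2, "passive": 3}


@pytest.mark.parametrize("speed,expected", [
    (0.0, 0), (0.5, 0), (0.99, 0),       # below movement threshold
    (1.0, 1), (5.0, 1), (9.99, 1),       # walking band is [1, 10)
    (10.0, 2), (24.99, 2),               # cycling band is [10, 25)
    (25.0, 3), (80.0, 3),                # passive transport >= 25
    (np.nan, 0),                         # no fix -> stationary
])
def test_speed_band_edges(speed, expected):
    assert classify_epoch_speed(speed) == expected


def test_negative_speed_rejected():
    with pytest.raises(ValueError):
        classify_epoch_speed(-1.0)


class TestSmoothing:
    def test_window_one_is_identity(self):
        s = np.array([0.0, 5.0, 80.0, 5.0, np.nan])
        assert np.array_equal(smooth_speeds(s, 1), s, equal_nan=True)

    def test_median_removes_isolated_spike(self):
        s = np.array([5.0] * 10)
        s[4] = 80.0
        out = smooth_speeds(s, 5)
        assert out[4] == 5.0

    def test_constant_series_unchanged(self):
        s = np.full(20, 7.0)
        for w in (1, 3, 5, 9):
            assert np.array_equal(smooth_speeds(s, w), s)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_speeds(np.zeros(5), 4)

    def test_nan_positions_preserved(self):
        s = np.array([5.0, np.nan, 5.0, 5.0, 5.0])
        out = smooth_speeds(s, 3)
        assert np.isnan(out[1]) and not np.isnan(out[0])


def _detect(speeds, **kw):
    return detect_trips(epochs_frame(speeds), CFG, smooth=False)


class TestSegmentation:
    def test_pause_within_allowance_merges(self):
        # 10 min walking, 4-min pause, 10 min walking -> one 24-min walk trip
        s = np.concatenate([np.full(40, 5.0), np.zeros(16), np.full(40, 5.0)])
        trips = _detect(s)
        assert len(trips) == 1
        assert trips[0].mode == "walk"
        assert trips[0].duration_min == pytest.approx(24.0)

    def test_pause_beyond_allowance_splits(self):
        # 6-min pause exceeds the 5-min stationary allowance -> two trips
        s = np.concatenate([np.full(40, 5.0), np.zeros(24), np.full(40, 5.0)])
        trips = _detect(s)
        assert [t.duration_min for t in trips] == [10.0, 10.0]
        assert all(t.mode == "walk" for t in trips)

    def test_below_minimum_duration_discarded(self):
        # 2.5 min of cycling surrounded by long stationarity -> no trip
        s = np.concatenate([np.zeros(100), np.full(10, 20.0), np.zeros(100)])
        assert _detect(s) == []

    def test_exactly_three_minutes_kept(self):
        s = np.concatenate([np.zeros(30), np.full(12, 20.0), np.zeros(30)])
        trips = _detect(s)
        assert len(trips) == 1 and trips[0].duration_min == pytest.approx(3.0)

    def test_sustained_band_change_splits_trip(self):
        # 5 min walking then 5 min cycling -> two trips of different mode
        s = np.concatenate([np.full(20, 5.0), np.full(20, 18.0)])
        trips = _detect(s)
        assert [t.mode for t in trips] == ["walk", "cycle"]

    def test_band_flicker_does_not_split(self):
        # two cycling epochs inside a walk do not fragment the trip
        s = np.full(40, 5.0)
        s[20:22] = 12.0
        trips = _detect(s)
        assert len(trips) == 1 and trips[0].mode == "walk"

    def test_dropout_gap_acts_as_stationary(self):
        # 4-min fix gap inside movement merges; 6-min gap splits
        merged = np.concatenate([np.full(40, 5.0), np.full(16, np.nan), np.full(40, 5.0)])
        split = np.concatenate([np.full(40, 5.0), np.full(24, np.nan), np.full(40, 5.0)])
        assert len(_detect(merged)) == 1
        assert len(_detect(split)) == 2


class TestTripInvariants:
    def test_detected_trips_satisfy_type_invariants(self):
        rng = np.random.default_rng(42)
        th = CFG.thresholds
        for _ in range(25):
            speeds = random_speed_stream(rng, 1500)
            for trip in _detect(speeds):
                assert trip.duration_min >= th.min_trip_min
                assert trip.end > trip.start
                med_band = int(classify_epoch_speed(trip.median_speed_kmh))
                assert MODE_CODE[trip.mode] == med_band

    def test_segmentation_idempotent_on_detected_trip(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            speeds = random_speed_stream(rng, 1000)
            frame = epochs_frame(speeds)
            for trip in detect_trips(frame, CFG, smooth=False):
                sub = frame[(frame["timestamp"] >= trip.start) & (frame["timestamp"] < trip.end)]
                again = detect_trips(sub, CFG, smooth=False)
                assert len(again) == 1
                assert again[0].mode == trip.mode
                assert again[0].duration_min == trip.duration_min


def assert_matches_reference(speeds, epoch_s=15):
    th = CFG.thresholds
    trips = _detect(speeds)
    tidx = np.arange(len(speeds))
    expected = ref_trips(tidx, speeds, epoch_s=epoch_s,
                         movement=th.movement_kmh, walk_max=th.walk_max_kmh,
                         cycle_max=th.cycle_max_kmh, min_trip_min=th.min_trip_min,
                         max_pause_min=th.max_pause_min,
                         persistence=th.split_persistence_epochs)
    got = [(int((t.start - pd.Timestamp("2014-01-07 10:00:00")).total_seconds() // epoch_s),
            int((t.end - pd.Timestamp("2014-01-07 10:00:00")).total_seconds() // epoch_s) - 1,
            MODE_CODE[t.mode]) for t in trips]
    assert got == expected


def test_oracle_equivalence_random_streams():
    """Segmentation matches the brute-force reference on random instances."""
    rng = np.random.default_rng(2024)
    for _ in range(60):
        assert_matches_reference(random_speed_stream(rng, int(rng.integers(50, 2000))))


def test_noise_free_recovery(noise_free_study):
    """Zero noise/dropout: detected trips match the manifest one-to-one."""
    study = noise_free_study
    det = trips_to_frame(detect_trips(study.epochs, study.study_config))
    truth = study.manifest.trips
    det = det.sort_values(["participant_id", "start"]).reset_index(drop=True)
    truth = truth.sort_values(["participant_id", "start"]).reset_index(drop=True)
    assert len(det) == len(truth)
    assert (det["mode"].to_numpy() == truth["mode"].to_numpy()).all()
    dur_err = np.abs(det["duration_min"].to_numpy() - truth["duration_min"].to_numpy())
    assert dur_err.max() <= 0.25 + 1e-9  # within one epoch
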