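"""Wear-time rules: non-wear runs, valid days, inclusion."""

import numpy as np
import pandas as pd
import pytest

from leisuregps.config import StudyConfig
from leisuregps.preprocess import detect_non_wear, flag_valid_days, include_participants, wear_mask

from conftest import epochs_frame
from reference import ref_nonwear_mask

CFG = StudyConfig()


def counts_frame(counts, pid="P1", start="2014-01-07 00:00:00"):
    f = epochs_frame(np.zeros(len(counts)), pid=pid, start=start)
    f["counts"] = np.asarray(counts, dtype=float)
    return f


class TestNonWear:
    def test_59_minutes_of_zeros_is_wear(self):
        counts = np.ones(1000)
        counts[100:100 + 236] = 0  # 59 min
        assert detect_non_wear(counts_frame(counts), CFG).empty

    def test_exactly_60_minutes_is_non_wear(self):
        counts = np.ones(1000)
        counts[100:100 + 240] = 0
        nw = detect_non_wear(counts_frame(counts), CFG)
        assert len(nw) == 1
        assert (nw["end"] - nw["start"]).iloc[0] == pd.Timedelta(minutes=60)

    def test_single_spike_breaks_the_run(self):
        # strict rule: one non-zero epoch splits a zero run into two halves
        counts = np.ones(1000)
        counts[100:340] = 0
        counts[220] = 5
        assert detect_non_wear(counts_frame(counts), CFG).empty

    def test_matches_brute_force_on_random_streams(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            n = int(rng.integers(300, 2000))
            # sparse non-zeros so long zero runs actually occur
            counts = (rng.random(n) < 0.004).astype(float) * rng.integers(1, 100, n)
            frame = counts_frame(counts)
            nw = detect_non_wear(frame, CFG)
            mask = np.zeros(n, dtype=bool)
            for r in nw.itertuples(index=False):
                i0 = int((r.start - frame["timestamp"].iloc[0]).total_seconds() // 15)
                i1 = int((r.end - frame["timestamp"].iloc[0]).total_seconds() // 15)
                mask[i0:i1] = True
            assert np.array_equal(mask, ref_nonwear_mask(counts))

    def test_wear_and_nonwear_partition_count_epochs(self):
        rng = np.random.default_rng(6)
        counts = (rng.random(1500) < 0.004).astype(float) * 50
        frame = counts_frame(counts)
        wear = wear_mask(frame, CFG).to_numpy()
        nonwear = ref_nonwear_mask(counts)
        assert np.array_equal(wear, ~nonwear)

    def test_adding_counts_never_decreases_wear(self):
        rng = np.random.default_rng(7)
        counts = (rng.random(2000) < 0.003).astype(float) * 50
        before = wear_mask(counts_frame(counts), CFG).sum()
        bumped = counts.copy()
        bumped[rng.integers(0, 2000, 10)] = 10
        after = wear_mask(counts_frame(bumped), CFG).sum()
        assert after >= before


def day_frame(specs):
    """specs: list of (pid, date, n_combined_epochs) -> aligned frame with
    that many simultaneous wear+fix epochs on the date (rest non-wear)."""
    frames = []
    for pid, date, n_combined in specs:
        n = 4000
        speeds = np.full(n, np.nan)
        speeds[:n_combined] = 0.0  # fix present
        f = epochs_frame(speeds, pid=pid, start=f"{date} 07:00:00")
        counts = np.zeros(n)
        counts[:n_combined] = 100
        f["counts"] = counts
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


class TestValidDays:
    def test_nine_hours_combined_is_valid(self):
        f = day_frame([("P1", "2014-01-07", 1), ("P1", "2014-01-08", 2160)])  # day 2: 9 h
        wd = flag_valid_days(f, CFG)
        assert wd.set_index("date")["is_valid"].to_dict() == {
            pd.Timestamp("2014-01-07").date(): False,
            pd.Timestamp("2014-01-08").date(): True,
        }

    def test_first_day_excluded_despite_wear(self):
        f = day_frame([("P1", "2014-01-07", 2880)])  # 12 h on the first day
        wd = flag_valid_days(f, CFG)
        assert not wd["is_valid"].any() and wd["is_first_day"].all()

    def test_combined_means_simultaneous_coverage(self):
        # 10 h accel wear but only 6 h with GPS fixes -> 6 h combined, invalid
        n = 4000
        speeds = np.full(n, np.nan)
        speeds[:1440] = 0.0           # 6 h of fixes
        f = epochs_frame(speeds, pid="P1", start="2014-01-08 07:00:00")
        counts = np.zeros(n)
        counts[:2400] = 100           # 10 h of wear
        f["counts"] = counts
        f2 = day_frame([("P1", "2014-01-07", 10)])  # day-1 stub
        wd = flag_valid_days(pd.concat([f2, f], ignore_index=True), CFG)
        row = wd[wd["date"] == pd.Timestamp("2014-01-08").date()].iloc[0]
        assert row["combined_wear_minutes"] == pytest.approx(360.0)
        assert not row["is_valid"]


class TestInclusion:
    @staticmethod
    def weardays(pid, valid_dates):
        rows = []
        all_dates = pd.date_range("2014-01-06", periods=8)  # Mon..Mon
        for i, d in enumerate(all_dates):
            rows.append({"participant_id": pid, "date": d.date(),
                         "combined_wear_minutes": 600 if d.date() in valid_dates else 0,
                         "is_weekend": d.weekday() >= 5, "is_first_day": i == 0,
                         "is_valid": d.date() in valid_dates and i > 0})
        return pd.DataFrame(rows)

    def test_four_weekdays_without_weekend_excluded(self):
        dates = {pd.Timestamp(f"2014-01-{d:02d}").date() for d in (7, 8, 9, 10)}
        inc = include_participants(self.weardays("P1", dates), CFG)
        assert not inc["included"].iloc[0]

    def test_three_weekdays_plus_weekend_day_included(self):
        dates = {pd.Timestamp(f"2014-01-{d:02d}").date() for d in (7, 8, 9, 11)}  # Sat 11th
        inc = include_participants(self.weardays("P1", dates), CFG)
        assert inc["included"].iloc[0]

    def test_synthetic_cohort_matches_manifest(self, noisy_study):
        wd = flag_valid_days(noisy_study.epochs, noisy_study.study_config)
        inc = include_participants(wd, noisy_study.study_config).sort_values("participant_id")
        expected = noisy_study.manifest.expected_inclusion().sort_values("participant_id")
        assert inc["included"].tolist() == expected["included"].tolist()
        assert inc["valid_days"].tolist() == expected["valid_days"].tolist()
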