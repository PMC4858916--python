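"""Wear-time detection and participant inclusion rules.

Non-wear is a run of 60 min or more of consecutive zero accelerometer
counts (strict rule, no spike tolerance). A valid day has at least 9 h of
*combined* coverage — epochs that are simultaneously accelerometer wear and
GPS-fixed — and is not the participant's first recorded calendar day (the
devices are handed out during day 1). Participants enter the analysis with
at least 4 valid days including at least one weekend day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import StudyConfig

WEARDAY_COLUMNS = [
    "participant_id", "date", "combined_wear_minutes", "is_weekend", "is_valid", "is_first_day",
]


def _zero_runs(values: np.ndarray, tidx: np.ndarray, min_epochs: int):
    """Maximal runs of consecutive (on the time grid) zero counts >= min_epochs.

    NaN counts and grid gaps both terminate a run. Yields (i0, i1) index
    pairs into ``values`` (inclusive).
    """
    is_zero = values == 0  # NaN compares False
    start = None
    for i in range(values.size):
        contiguous = start is not None and tidx[i] == tidx[i - 1] + 1
        if is_zero[i] and contiguous:
            continue
        if start is not None and is_zero[start]:
            if tidx[i - 1] - tidx[start] + 1 >= min_epochs:
                yield start, i - 1
        start = i if is_zero[i] else None
    if start is not None and is_zero[start] and tidx[values.size - 1] - tidx[start] + 1 >= min_epochs:
        yield start, values.size - 1


def detect_non_wear(epochs: pd.DataFrame, config: StudyConfig | None = None) -> pd.DataFrame:
    """Non-wear intervals (>=60 min of zero counts) per participant.

    Returns a frame ``participant_id,start,end`` with end exclusive
    (end of the last zero epoch).
    """
    config = config or StudyConfig()
    min_epochs = int(round(config.thresholds.nonwear_min * 60 / config.epoch_s))
    rows = []
    for pid, grp in epochs.groupby("participant_id", observed=True, sort=True):
        grp = grp.sort_values("timestamp")
        counts = grp["counts"].to_numpy(dtype=float)
        tidx = (grp["timestamp"].astype("int64") // (config.epoch_s * 1_000_000_000)).to_numpy()
        ts = grp["timestamp"].to_numpy()
        for i0, i1 in _zero_runs(counts, tidx, min_epochs):
            rows.append({
                "participant_id": str(pid),
                "start": pd.Timestamp(ts[i0]),
                "end": pd.Timestamp(ts[i1]) + pd.Timedelta(seconds=config.epoch_s),
            })
    return pd.DataFrame(rows, columns=["participant_id", "start", "end"])


def wear_mask(epochs: pd.DataFrame, config: StudyConfig | None = None) -> pd.Series:
    """Boolean accelerometer-wear flag per epoch row (aligned to ``epochs``)."""
    config = config or StudyConfig()
    nonwear = detect_non_wear(epochs, config)
    mask = epochs["counts"].notna().to_numpy()
    by_pid = {pid: grp for pid, grp in nonwear.groupby("participant_id", observed=True)}
    for pid, grp in epochs.groupby("participant_id", observed=True):
        if pid not in by_pid:
            continue
        order = np.argsort(grp["timestamp"].to_numpy())
        ts = grp["timestamp"].to_numpy()[order]
        rows = grp.index.to_numpy()[order]
        local = np.ones(ts.size, dtype=bool)
        for r in by_pid[pid].itertuples(index=False):
            i0 = np.searchsorted(ts, np.datetime64(r.start), side="left")
            i1 = np.searchsorted(ts, np.datetime64(r.end), side="left")
            local[i0:i1] = False
        pos = epochs.index.get_indexer(rows)
        mask[pos] &= local
    return pd.Series(mask, index=epochs.index)


def flag_valid_days(epochs: pd.DataFrame, config: StudyConfig | None = None) -> pd.DataFrame:
    """Per participant x calendar date wear summary with validity flags."""
    config = config or StudyConfig()
    th = config.thresholds
    df = epochs[["participant_id", "timestamp"]].copy()
    df["combined"] = wear_mask(epochs, config) & epochs["lat"].notna()
    df["date"] = df["timestamp"].dt.date
    day = (
        df.groupby(["participant_id", "date"], observed=True)["combined"]
        .sum()
        .mul(config.epoch_s / 60.0)
        .rename("combined_wear_minutes")
        .reset_index()
    )
    first = day.groupby("participant_id", observed=True)["date"].transform("min")
    day["is_weekend"] = pd.to_datetime(day["date"]).dt.weekday >= 5
    day["is_first_day"] = day["date"] == first
    day["is_valid"] = (day["combined_wear_minutes"] >= th.min_wear_hours * 60) & ~day["is_first_day"]
    return day[WEARDAY_COLUMNS]


def include_participants(weardays: pd.DataFrame, config: StudyConfig | None = None) -> pd.DataFrame:
    """Inclusion table: >= min_valid_days valid days incl. >= min_weekend_days weekend days."""
    config = config or StudyConfig()
    th = config.thresholds
    valid = weardays[weardays["is_valid"]]
    n_valid = valid.groupby("participant_id", observed=True).size()
    n_weekend = valid[valid["is_weekend"]].groupby("participant_id", observed=True).size()
    out = pd.DataFrame({"participant_id": weardays["participant_id"].unique()})
    out["valid_days"] = out["participant_id"].map(n_valid).fillna(0).astype(int)
    out["valid_weekend_days"] = out["participant_id"].map(n_weekend).fillna(0).astype(int)
    out["included"] = (out["valid_days"] >= th.min_valid_days) & (
        out["valid_weekend_days"] >= th.min_weekend_days
    )
    return out
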