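"""Readers and writers for the pipeline's tabular formats.

GPS and accelerometer streams arrive as CSV (one row per device sample);
GPX 1.1 is also accepted for GPS tracks. Both streams are aligned onto a
common epoch grid (timestamps floored to the epoch start) so that every
grid point covered by either stream yields one epoch record, with absent
fields on the side that produced no sample.

CSV dialects
------------
GPS:            participant_id,timestamp,lat,lon,speed_kmh
accelerometer:  participant_id,timestamp,counts
diary:          participant_id,date,mode,is_school_trip
questionnaire:  participant_id,<item columns>,age,sex,ses
Timestamps are ISO-8601 in the (single) study-local timezone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .config import StudyConfig
from .util import haversine_m

logger = logging.getLogger(__name__)

EPOCH_COLUMNS = ["participant_id", "timestamp", "lat", "lon", "speed_kmh", "counts"]

#: diary mode codes accepted on input -> canonical mode
DIARY_MODE_MAP = {
    "walk": "walk", "walking": "walk",
    "cycle": "cycle", "cycling": "cycle", "bike": "cycle",
    "car": "passive", "public transport": "passive", "public_transport": "passive",
    "bus": "passive", "train": "passive", "passive": "passive",
}


def _check_coordinates(df: pd.DataFrame, source: str) -> pd.DataFrame:
    bad = (df["lat"].abs() > 90) | (df["lon"].abs() > 180)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: rejected %d records with out-of-range coordinates", source, n_bad)
        df = df.loc[~bad]
    return df


def _reject_duplicates(df: pd.DataFrame, source: str) -> None:
    dup = df.duplicated(["participant_id", "timestamp"], keep=False)
    if dup.any():
        report = (
            df.loc[dup]
            .groupby("participant_id", observed=True)["timestamp"]
            .agg(["count", "min", "max"])
        )
        raise ValueError(
            f"{source}: duplicate timestamps after flooring to the epoch grid:\n{report}"
        )


def read_gpx(path) -> pd.DataFrame:
    """Parse a GPX 1.1 file into the GPS CSV schema (one participant per file).

    The participant id is the track ``<name>`` (file stem if absent).
    Speed is left absent; it is recomputed from consecutive fixes downstream.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()

    def findall(node, tag):
        return node.findall(f".//{{*}}{tag}")

    rows = []
    for trk in findall(root, "trk"):
        names = trk.findall("{*}name")
        pid = names[0].text.strip() if names and names[0].text else Path(path).stem
        for pt in findall(trk, "trkpt"):
            t = pt.findall("{*}time")
            if not t or t[0].text is None:
                continue
            rows.append({
                "participant_id": pid,
                "timestamp": pd.Timestamp(t[0].text.strip()).tz_localize(None)
                if pd.Timestamp(t[0].text.strip()).tzinfo is None
                else pd.Timestamp(t[0].text.strip()).tz_convert(None),
                "lat": float(pt.get("lat")),
                "lon": float(pt.get("lon")),
                "speed_kmh": np.nan,
            })
    return pd.DataFrame(rows, columns=["participant_id", "timestamp", "lat", "lon", "speed_kmh"])


def _read_gps(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".gpx":
        gps = read_gpx(path)
    else:
        gps = pd.read_csv(path)
        gps["timestamp"] = pd.to_datetime(gps["timestamp"])
        if "speed_kmh" not in gps.columns:
            gps["speed_kmh"] = np.nan
    gps["participant_id"] = gps["participant_id"].astype(str)
    return _check_coordinates(gps, str(path))


def _recompute_missing_speeds(gps: pd.DataFrame, epoch_s: int) -> pd.DataFrame:
    """Fill absent speeds from consecutive fixes: great-circle distance / elapsed time."""
    if gps["speed_kmh"].notna().all() or gps.empty:
        return gps
    gps = gps.sort_values(["participant_id", "timestamp"]).reset_index(drop=True)
    grp = gps.groupby("participant_id", observed=True)
    plat, plon = grp["lat"].shift(), grp["lon"].shift()
    dt_s = (gps["timestamp"] - grp["timestamp"].shift()).dt.total_seconds()
    dist = haversine_m(plat.fillna(gps["lat"]), plon.fillna(gps["lon"]), gps["lat"], gps["lon"])
    derived = np.where(dt_s > 0, dist / dt_s * 3.6, 0.0)
    need = gps["speed_kmh"].isna() & gps["lat"].notna()
    gps.loc[need, "speed_kmh"] = derived[need.to_numpy()]
    return gps


def read_epochs(gps_path, accel_path, config: StudyConfig) -> pd.DataFrame:
    """Read GPS + accelerometer streams and align them on the common epoch grid.

    Returns one row per (participant, grid timestamp) covered by either
    stream, sorted by participant then time. GPS-less epochs carry NaN
    lat/lon/speed; counts are NaN where the accelerometer produced no sample.
    """
    epoch_s = config.epoch_s
    gps = _read_gps(gps_path)
    gps["timestamp"] = gps["timestamp"].dt.floor(f"{epoch_s}s")
    _reject_duplicates(gps, str(gps_path))
    gps = _recompute_missing_speeds(gps, epoch_s)
    if (gps["speed_kmh"] < 0).any():
        raise ValueError(f"{gps_path}: negative speeds")

    accel = pd.read_csv(accel_path)
    accel["participant_id"] = accel["participant_id"].astype(str)
    accel["timestamp"] = pd.to_datetime(accel["timestamp"]).dt.floor(f"{epoch_s}s")
    _reject_duplicates(accel, str(accel_path))
    if (accel["counts"] < 0).any():
        raise ValueError(f"{accel_path}: negative counts")

    epochs = gps[["participant_id", "timestamp", "lat", "lon", "speed_kmh"]].merge(
        accel[["participant_id", "timestamp", "counts"]],
        on=["participant_id", "timestamp"],
        how="outer",
    )
    # speed is meaningless without a fix
    epochs.loc[epochs["lat"].isna(), "speed_kmh"] = np.nan
    epochs = epochs.sort_values(["participant_id", "timestamp"], kind="mergesort")
    return epochs.reset_index(drop=True)[EPOCH_COLUMNS]


def read_diary(path) -> pd.DataFrame:
    """Read the self-report diary; car/public-transport codes map to ``passive``.

    Rows with unknown mode codes are rejected (logged); school trips are
    retained but flagged so downstream analyses can exclude them.
    """
    diary = pd.read_csv(path)
    if diary.empty:
        logger.warning("%s: empty diary", path)
        return pd.DataFrame(columns=["participant_id", "date", "mode", "is_school_trip"])
    diary["participant_id"] = diary["participant_id"].astype(str)
    diary["date"] = pd.to_datetime(diary["date"]).dt.date
    mode = diary["mode"].astype(str).str.strip().str.lower().map(DIARY_MODE_MAP)
    bad = mode.isna()
    if bad.any():
        logger.warning("%s: rejected %d diary rows with unknown mode codes", path, int(bad.sum()))
    diary = diary.loc[~bad].copy()
    diary["mode"] = mode[~bad]
    diary["is_school_trip"] = diary["is_school_trip"].astype(bool)
    return diary.reset_index(drop=True)[["participant_id", "date", "mode", "is_school_trip"]]


def read_questionnaire(path) -> pd.DataFrame:
    q = pd.read_csv(path)
    q["participant_id"] = q["participant_id"].astype(str)
    return q


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path, parse_dates=()) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in parse_dates:
        df[col] = pd.to_datetime(df[col])
    if "participant_id" in df.columns:
        df["participant_id"] = df["participant_id"].astype(str)
    return df
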