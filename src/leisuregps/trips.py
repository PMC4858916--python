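"""Trip detection and travel-mode classification from epoch speed series.

A trip is a continuous period of movement in one transport mode lasting at
least 3 min, tolerating internal stationary periods of at most 5 min.
Epoch speeds are banded as stationary (<1 km/h), walking (1 to <10 km/h),
cycling (10 to <25 km/h) or passive/vehicle transport (>=25 km/h); the trip
mode is the band of the median speed over its moving epochs.

Detection proceeds in three steps:

1. *Runs*: moving epochs are chained into movement runs, merging across
   stationary (or GPS-less) gaps of at most the pause allowance; a longer
   gap terminates the run.
2. *Splits*: a run is split where the speed band changes and the new band
   persists for at least ``split_persistence_epochs`` consecutive moving
   epochs (1 min at 15-s epochs); shorter excursions — a cyclist slowing
   through the walking band, a GPS speed spike — do not fragment the trip.
3. *Minimum duration*: segments whose total extent (first to last moving
   epoch, internal pauses included) is shorter than the trip minimum are
   discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import StudyConfig, Thresholds

MODE_NAMES = {1: "walk", 2: "cycle", 3: "passive"}

TRIP_COLUMNS = [
    "participant_id", "start", "end", "mode", "duration_min", "median_speed_kmh",
    "start_lat", "start_lon", "end_lat", "end_lon",
]


@dataclass(frozen=True)
class Trip:
    """One detected movement bout with a mode label."""

    participant_id: str
    start: pd.Timestamp          # start of the first moving epoch
    end: pd.Timestamp            # end of the last moving epoch
    mode: str                    # walk | cycle | passive
    duration_min: float          # total extent incl. internal pauses
    median_speed_kmh: float      # median over moving epochs
    start_lat: float
    start_lon: float
    end_lat: float
    end_lon: float

    @property
    def midpoint(self) -> pd.Timestamp:
        return self.start + (self.end - self.start) / 2


def classify_epoch_speed(speed_kmh, thresholds: Thresholds | None = None):
    """Band code per epoch speed: 0 stationary, 1 walk, 2 cycle, 3 passive.

    Absent (NaN) speeds — no GPS fix — are stationary. Negative speeds are
    rejected.
    """
    th = thresholds or Thresholds()
    s = np.asarray(speed_kmh, dtype=float)
    if np.any(s[~np.isnan(s)] < 0):
        raise ValueError("negative speed")
    band = np.zeros(s.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        band[s >= th.movement_kmh] = 1
        band[s >= th.walk_max_kmh] = 2
        band[s >= th.cycle_max_kmh] = 3
    band[np.isnan(s)] = 0
    return band if band.ndim else np.int8(band)


def smooth_speeds(speed_kmh, window: int = 5):
    """Centred running median of the speed series; ``window`` must be odd.

    The window is truncated at the edges, NaNs (no fix) are ignored inside a
    window and preserved in place, so smoothing never invents fixes.
    ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    s = np.asarray(speed_kmh, dtype=float)
    if window == 1 or s.size == 0:
        return s.copy()
    half = window // 2
    padded = np.concatenate([np.full(half, np.nan), s, np.full(half, np.nan)])
    windows = np.lib.stride_tricks.sliding_window_view(padded, window)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = np.nanmedian(windows, axis=1)
    out[np.isnan(s)] = np.nan
    return out


def _segment_run(bands: np.ndarray, persistence: int) -> list[np.ndarray]:
    """Split a run's moving-epoch band sequence at sustained band changes.

    Maximal same-band blocks of length >= ``persistence`` are *sustained*;
    shorter blocks attach to the preceding sustained block (or the following
    one at the head of the run). Splits fall exactly where the owning
    sustained band changes. Returns index arrays into the run.
    """
    m = bands.size
    edges = np.flatnonzero(np.diff(bands)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [m]))
    lengths = ends - starts
    sustained = lengths >= persistence
    if not sustained.any():
        return [np.arange(m)]
    owner = np.full(starts.size, -1)
    last = -1
    for i in range(starts.size):
        if sustained[i]:
            last = i
        owner[i] = last
    first_sus = np.flatnonzero(sustained)[0]
    owner[owner == -1] = first_sus  # leading short blocks join the first sustained block
    segments = []
    seg_start = 0
    for i in range(1, starts.size):
        if bands[starts[owner[i]]] != bands[starts[owner[i - 1]]]:
            segments.append(np.arange(seg_start, starts[i]))
            seg_start = starts[i]
    segments.append(np.arange(seg_start, m))
    return segments


def _detect_one(df: pd.DataFrame, config: StudyConfig) -> list[Trip]:
    th = config.thresholds
    epoch_s = config.epoch_s
    pid = str(df["participant_id"].iloc[0])
    speeds = df["speed_kmh"].to_numpy(dtype=float)
    bands = classify_epoch_speed(speeds, th)
    moving = np.flatnonzero(bands > 0)
    if moving.size == 0:
        return []

    # time index on the epoch grid (robust to missing grid rows)
    tidx = (df["timestamp"].astype("int64") // (epoch_s * 1_000_000_000)).to_numpy()
    gap_epochs = int(round(th.max_pause_min * 60 / epoch_s))
    min_epochs = int(np.ceil(th.min_trip_min * 60 / epoch_s))

    t_mov = tidx[moving]
    run_breaks = np.flatnonzero(np.diff(t_mov) - 1 > gap_epochs) + 1
    runs = np.split(np.arange(moving.size), run_breaks)

    trips: list[Trip] = []
    lat = df["lat"].to_numpy(dtype=float)
    lon = df["lon"].to_numpy(dtype=float)
    ts = df["timestamp"].to_numpy()
    for run in runs:
        run_rows = moving[run]
        for seg in _segment_run(bands[run_rows], th.split_persistence_epochs):
            rows = run_rows[seg]
            extent_epochs = tidx[rows[-1]] - tidx[rows[0]] + 1
            if extent_epochs < min_epochs:
                continue
            med = float(np.median(speeds[rows]))
            mode = MODE_NAMES[int(classify_epoch_speed(med, th))]
            trips.append(Trip(
                participant_id=pid,
                start=pd.Timestamp(ts[rows[0]]),
                end=pd.Timestamp(ts[rows[-1]]) + pd.Timedelta(seconds=epoch_s),
                mode=mode,
                duration_min=extent_epochs * epoch_s / 60.0,
                median_speed_kmh=med,
                start_lat=lat[rows[0]], start_lon=lon[rows[0]],
                end_lat=lat[rows[-1]], end_lon=lon[rows[-1]],
            ))
    return trips


def detect_trips(epochs: pd.DataFrame, config: StudyConfig | None = None,
                 smooth: bool | None = None) -> list[Trip]:
    """Detect trips for every participant in an aligned epoch frame.

    ``smooth`` applies the configured running-median speed filter first
    (default: on when ``thresholds.smooth_window > 1``).
    """
    config = config or StudyConfig()
    if epochs.empty:
        return []
    if smooth is None:
        smooth = config.thresholds.smooth_window > 1
    trips: list[Trip] = []
    for _, grp in epochs.groupby("participant_id", observed=True, sort=True):
        grp = grp.sort_values("timestamp")
        if smooth and config.thresholds.smooth_window > 1:
            grp = grp.copy()
            grp["speed_kmh"] = smooth_speeds(
                grp["speed_kmh"].to_numpy(), config.thresholds.smooth_window
            )
        trips.extend(_detect_one(grp, config))
    return trips


def trips_to_frame(trips: list[Trip]) -> pd.DataFrame:
    if not trips:
        return pd.DataFrame(columns=TRIP_COLUMNS)
    df = pd.DataFrame([t.__dict__ for t in trips])
    return df[TRIP_COLUMNS]


def trips_from_frame(df: pd.DataFrame) -> list[Trip]:
    return [
        Trip(participant_id=str(r.participant_id), start=pd.Timestamp(r.start),
             end=pd.Timestamp(r.end), mode=r.mode, duration_min=float(r.duration_min),
             median_speed_kmh=float(r.median_speed_kmh),
             start_lat=float(r.start_lat), start_lon=float(r.start_lon),
             end_lat=float(r.end_lat), end_lon=float(r.end_lon))
        for r in df.itertuples(index=False)
    ]
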