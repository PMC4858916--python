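"""Synthetic-study generator with a ground-truth manifest.

Produces complete studies — 15-s epoch GPS tracks with walking/cycling/
vehicle trips, stationary pauses, positional noise and dropouts;
accelerometer count streams with wear/non-wear blocks; under-reported trip
diaries; parental questionnaires whose subscales are linked to transport
outcomes — so that every pipeline stage can be tested against known truth.

Trips are placed by a thinned Poisson process inside eligible (wear x
leisure) windows, with a separation buffer larger than the stationary
allowance so that distinct true trips can never merge. School days gain
morning and afternoon home<->school commutes (Wednesday afternoons at the
early close). Positional noise is isotropic Gaussian in a local metric
frame with the GPS receiver's 2.9-m median dynamic error as default.

Diaries model the under-reporting seen when children self-report: active
trips are reported with low probability (default 0.2) while passive trips
are reported reliably (0.9) and occasionally split into two entries
(combined trips appear as multiple diary rows).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as date_cls, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import GeoAnchor, SchoolSchedule, StudyConfig, Thresholds
from .envscores import DEFAULT_ITEM_SETS, MEAN_SUBSCALES
from .util import haversine_m, offset_latlon

EPOCHS_PER_DAY = 24 * 60 * 4  # at 15 s

MODES = ("walk", "cycle", "passive")


@dataclass
class SynthConfig:
    """Study conditions of the generator (defaults emulate the target cohort:
    one winter week of 10-12-year-olds, two weekend days, suburban/urban
    Belgian schools)."""

    n_participants: int = 30
    n_classes: int = 6
    n_schools: int = 2
    days: int = 7                      # starting on a Monday -> 2 weekend days
    start_date: date_cls = date_cls(2013, 12, 2)
    epoch_s: int = 15

    # trips/day Poisson intensities per mode x (week, weekend)
    trip_rates: dict = field(default_factory=lambda: {
        "walk": (4.0, 1.6), "cycle": (1.2, 0.9), "passive": (1.9, 2.1),
    })
    # per-mode epoch-speed (mean, jitter sd) in km/h; bands are taken from Thresholds
    speed_params: dict = field(default_factory=lambda: {
        "walk": (4.5, 1.2), "cycle": (15.0, 2.5), "passive": (40.0, 7.0),
    })
    band_leak_p: float = 0.02          # chance an epoch speed is drawn unclamped
    trip_extent_min: dict = field(default_factory=lambda: {
        "walk": (3.5, 11.0), "cycle": (3.5, 10.0), "passive": (4.0, 14.0),
    })
    pause_rate: float = 0.3            # expected pauses per trip
    pause_len_min: tuple = (0.5, 4.5)  # within the 5-min stationary allowance

    gps_dropout_p: float = 0.05        # per-epoch missing-fix probability
    positional_noise_m: float = 2.9    # isotropic Gaussian sd
    stationary_speed_max: float = 0.95 # residual speed noise while stationary

    wear_start: tuple = (7.5, 0.25)    # hours (mean, sd), snapped to grid
    wear_end: tuple = (21.5, 0.25)
    extra_nonwear_p: float = 0.15      # chance/day of a >=60-min zero block in the wear window
    extra_nonwear_min: tuple = (60.0, 100.0)
    bad_day_p: float = 0.05            # whole-day GPS failure
    frac_low_wear: float = 0.1         # participants engineered to fail inclusion

    # diary model
    report_prob: dict = field(default_factory=lambda: {"walk": 0.2, "cycle": 0.2, "passive": 0.9})
    passive_split_p: float = 0.1       # reported passive trip recorded as two entries
    school_trip_report_p: float = 0.95

    # questionnaire linkage (log-rate coefficients on standardised subscales)
    env_effects: dict = field(default_factory=lambda: {
        "walk": {"aesthetics": 0.10, "residential_density": 0.08},
        "cycle": {"land_use_mix_access": 0.12},
        "passive": {},
    })
    engage_prob: dict = field(default_factory=lambda: {
        "walk": (0.995, 0.85), "cycle": (0.9, 0.7), "passive": (0.9, 0.85),
    })
    class_re_sd: float = 0.15          # log-rate class random intercept
    class_re_sd_engage: float = 0.3    # logit-scale class random intercept

    school_commutes: bool = True
    seed: int = 0

    def __post_init__(self):
        for p in (self.gps_dropout_p, self.band_leak_p, self.extra_nonwear_p,
                  self.bad_day_p, self.passive_split_p, *self.report_prob.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def noise_free(cls, **kw) -> "SynthConfig":
        """The noise-free limit: no dropout, no positional or speed noise,
        no pauses, no band leakage — every true trip is an uninterrupted
        constant-band speed run."""
        kw.setdefault("gps_dropout_p", 0.0)
        kw.setdefault("positional_noise_m", 0.0)
        kw.setdefault("stationary_speed_max", 0.0)
        kw.setdefault("band_leak_p", 0.0)
        kw.setdefault("pause_rate", 0.0)
        kw.setdefault("bad_day_p", 0.0)
        kw.setdefault("extra_nonwear_p", 0.0)
        cfg = cls(**kw)
        cfg.speed_params = {m: (mu, 0.0) for m, (mu, sd) in cfg.speed_params.items()}
        return cfg


# --- standardisation constants for the env linkage (design constants) -----
_ENV_CENTER = {"residential_density": 60.0, **{s: 2.5 for s in MEAN_SUBSCALES}}
_ENV_SCALE = {"residential_density": 30.0, **{s: 0.5 for s in MEAN_SUBSCALES}}


@dataclass
class TruthManifest:
    """Ground truth of a simulated study."""

    trips: pd.DataFrame        # participant_id,date,start,end,mode,is_school_trip,duration_min
    valid_days: pd.DataFrame   # participant_id,date,is_weekend,is_first_day,is_valid,combined_wear_minutes
    wear_blocks: pd.DataFrame  # participant_id,date,wear_start,wear_end (designed wear window)
    coefficients: dict         # env linkage used
    meta: dict                 # grid_points per participant, seed, ...

    def leisure_trips(self) -> pd.DataFrame:
        return self.trips[~self.trips["is_school_trip"]].reset_index(drop=True)

    def expected_outcomes(self) -> pd.DataFrame:
        """Per participant x stratum x mode trips/day and min/day recomputed
        directly from the manifest (valid-day means; independent arithmetic)."""
        vd = self.valid_days[self.valid_days["is_valid"]].copy()
        vd["stratum"] = np.where(pd.to_datetime(vd["date"]).dt.weekday >= 5, "weekend", "week")
        denom = vd.groupby(["participant_id", "stratum"]).size()
        lt = self.leisure_trips().copy()
        valid_set = set(zip(vd["participant_id"], pd.to_datetime(vd["date"]).dt.date))
        lt = lt[[(p, pd.Timestamp(d).date()) in valid_set
                 for p, d in zip(lt["participant_id"], lt["date"])]]
        lt["stratum"] = np.where(pd.to_datetime(lt["date"]).dt.weekday >= 5, "weekend", "week")
        rows = []
        for (pid, stratum), n_days in denom.items():
            for mode in MODES:
                sub = lt[(lt["participant_id"] == pid) & (lt["stratum"] == stratum)
                         & (lt["mode"] == mode)]
                rows.append({
                    "participant_id": pid, "stratum": stratum, "mode": mode,
                    "trips_per_day": len(sub) / n_days,
                    "minutes_per_day": sub["duration_min"].sum() / n_days,
                    "engaged": len(sub) > 0,
                })
        return pd.DataFrame(rows)

    def expected_inclusion(self, min_valid_days=4, min_weekend_days=1) -> pd.DataFrame:
        vd = self.valid_days
        rows = []
        for pid, grp in vd.groupby("participant_id"):
            ok = grp["is_valid"]
            n_valid = int(ok.sum())
            n_we = int((ok & grp["is_weekend"]).sum())
            rows.append({"participant_id": pid, "valid_days": n_valid,
                         "valid_weekend_days": n_we,
                         "included": n_valid >= min_valid_days and n_we >= min_weekend_days})
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trips.to_csv(outdir / "manifest_trips.csv", index=False)
        self.valid_days.to_csv(outdir / "manifest_valid_days.csv", index=False)
        self.wear_blocks.to_csv(outdir / "manifest_wear_blocks.csv", index=False)
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(
            {"coefficients": self.coefficients, "meta": self.meta}, sort_keys=False))


@dataclass
class SimulatedStudy:
    """A complete simulated study plus the pipeline inputs it serialises to."""

    epochs: pd.DataFrame          # aligned union grid (what read_epochs returns)
    gps: pd.DataFrame             # device GPS rows (fix-bearing epochs only)
    accel: pd.DataFrame           # full-grid count rows
    diary: pd.DataFrame
    questionnaire: pd.DataFrame
    manifest: TruthManifest
    study_config: StudyConfig
    config: SynthConfig

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gps": outdir / "gps.csv", "accel": outdir / "accel.csv",
            "diary": outdir / "diary.csv", "questionnaire": outdir / "questionnaire.csv",
            "study_config": outdir / "study_config.yaml",
        }
        self.gps.to_csv(paths["gps"], index=False)
        self.accel.to_csv(paths["accel"], index=False)
        self.diary.to_csv(paths["diary"], index=False)
        self.questionnaire.to_csv(paths["questionnaire"], index=False)
        self.study_config.save(paths["study_config"])
        self.manifest.write(outdir)
        return {k: str(v) for k, v in paths.items()}


def _snap_min_to_epoch(minutes: float, epoch_s: int) -> int:
    """Minutes-from-midnight -> epoch index."""
    return int(round(minutes * 60 / epoch_s))


def _draw_speeds(rng, mode, n, cfg: SynthConfig, th: Thresholds):
    mu, sd = cfg.speed_params[mode]
    lo, hi = {
        "walk": (th.movement_kmh, th.walk_max_kmh),
        "cycle": (th.walk_max_kmh, th.cycle_max_kmh),
        "passive": (th.cycle_max_kmh, 90.0),
    }[mode]
    if sd == 0:
        return np.full(n, mu)
    s = rng.normal(mu, sd, size=n)
    margin = 0.05 * (hi - lo)
    clamped = np.clip(s, lo + margin, hi - margin)
    leak = rng.random(n) < cfg.band_leak_p
    return np.where(leak, np.maximum(s, 0.0), clamped)


def _place_interval(rng, windows, occupied, extent_ep, buffer_ep, tries=30):
    """Sample a start epoch so [start, start+extent) fits a window and keeps
    ``buffer_ep`` clearance from occupied intervals. None if it cannot fit."""
    fits = [(a, b) for a, b in windows if b - a >= extent_ep]
    if not fits:
        return None
    weights = np.array([b - a - extent_ep + 1 for a, b in fits], dtype=float)
    for _ in range(tries):
        wi = rng.choice(len(fits), p=weights / weights.sum())
        a, b = fits[wi]
        s = int(rng.integers(a, b - extent_ep + 1))
        e = s + extent_ep
        if all(e + buffer_ep <= o0 or s >= o1 + buffer_ep for o0, o1 in occupied):
            occupied.append((s, e))
            return s
    return None


@dataclass
class _TripPlan:
    start_ep: int
    extent_ep: int
    mode: str
    is_school_trip: bool
    pauses: list          # (offset_ep, len_ep) within the trip
    origin: str           # 'home' | 'school' | 'out'
    dest: str


def _plan_pauses(rng, extent_ep, cfg: SynthConfig):
    if cfg.pause_rate <= 0:
        return []
    n = rng.poisson(cfg.pause_rate)
    pauses, used = [], []
    for _ in range(n):
        plen = int(round(rng.uniform(*cfg.pause_len_min) * 60 / cfg.epoch_s))
        plen = max(plen, 1)
        if extent_ep - plen < 8:  # keep >=2 min of movement
            continue
        for _try in range(10):
            off = int(rng.integers(2, extent_ep - plen - 2)) if extent_ep - plen - 2 > 2 else None
            if off is None:
                break
            if all(off + plen + 1 < u0 or off > u1 + 1 for u0, u1 in used):
                pauses.append((off, plen))
                used.append((off, off + plen))
                break
    return sorted(pauses)


def simulate_study(cfg: SynthConfig) -> SimulatedStudy:
    """Generate a full synthetic study; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    th = Thresholds()
    epw = cfg.epoch_s
    n_per_day = 24 * 3600 // epw

    # --- cohort structure -------------------------------------------------
    pids = [f"P{i:03d}" for i in range(1, cfg.n_participants + 1)]
    class_ids = [f"C{i % cfg.n_classes + 1:02d}" for i in range(cfg.n_participants)]
    school_of_class = {f"C{c + 1:02d}": f"S{c % cfg.n_schools + 1}" for c in range(cfg.n_classes)}
    schools = {f"S{s + 1}": SchoolSchedule.regular(f"S{s + 1}",
                                                   start="08:30" if s % 2 == 0 else "08:15",
                                                   end="15:45" if s % 2 == 0 else "16:00")
               for s in range(cfg.n_schools)}
    school_latlon = {sid: (51.0 + 0.05 * i, 3.7 + 0.05 * i) for i, sid in enumerate(schools)}

    # questionnaires -------------------------------------------------------
    questionnaire = _simulate_questionnaire(rng, pids, class_ids, school_of_class, cfg)
    env_z = _standardised_scores(questionnaire)

    class_re = {c: rng.normal(0, cfg.class_re_sd) for c in sorted(set(class_ids))}
    class_re_eng = {c: rng.normal(0, cfg.class_re_sd_engage) for c in sorted(set(class_ids))}

    low_wear = set(rng.choice(pids, size=int(round(cfg.frac_low_wear * len(pids))),
                              replace=False)) if cfg.frac_low_wear > 0 else set()

    anchors = {}
    study_cfg_anchor_rows = {}
    trips_rows, wear_rows, valid_rows, diary_rows = [], [], [], []
    gps_frames, accel_frames = [], []

    dates = [cfg.start_date + timedelta(days=d) for d in range(cfg.days)]

    # feasibility: total demanded trip time vs leisure capacity
    for mode in MODES:
        wk, we = cfg.trip_rates[mode]
        mean_ext = np.mean(cfg.trip_extent_min[mode])
        if wk * (mean_ext + 6) > 7 * 60 or we * (mean_ext + 6) > 13 * 60:
            raise ValueError(f"infeasible config: {mode} trip rate too high for the day length")

    for pid, class_id in zip(pids, class_ids):
        school_id = school_of_class[class_id]
        sched = schools[school_id]
        s_lat, s_lon = school_latlon[school_id]
        # home 400-1500 m from school, random bearing
        hd = rng.uniform(400, 1500)
        hb = rng.uniform(0, 2 * math.pi)
        h_lat, h_lon = offset_latlon(s_lat, s_lon, hd * math.sin(hb), hd * math.cos(hb))
        anchors[pid] = {"home": GeoAnchor("home", float(h_lat), float(h_lon), th.geofence_m),
                        "school": GeoAnchor("school", float(s_lat), float(s_lon), th.geofence_m)}
        commute_mode = "walk" if hd < 900 else "cycle"
        commute_speed = cfg.speed_params[commute_mode][0]
        commute_ep = max(int(math.ceil(hd / 1000 / commute_speed * 60 / (epw / 60))), 14)

        # engagement per mode x stratum
        engaged = {}
        for mode in MODES:
            for si, stratum in enumerate(("week", "weekend")):
                base = cfg.engage_prob[mode][si]
                logit = math.log(base / (1 - base)) if base < 1 else 12.0
                logit += class_re_eng[class_id]
                engaged[(mode, stratum)] = rng.random() < 1 / (1 + math.exp(-logit))

        rate_mult = {}
        for mode in MODES:
            lin = sum(b * env_z.loc[pid, sub] for sub, b in cfg.env_effects.get(mode, {}).items())
            rate_mult[mode] = math.exp(lin + class_re[class_id])

        low_days = set(rng.choice(cfg.days, size=3, replace=False)) if pid in low_wear else set()

        for di, date in enumerate(dates):
            is_weekend = date.weekday() >= 5
            stratum = "weekend" if is_weekend else "week"
            hours = sched.for_date(date)

            if di in low_days:
                w0h, w1h = 9.0, 15.0   # engineered short wear
            else:
                w0h = rng.normal(*cfg.wear_start)
                w1h = rng.normal(*cfg.wear_end)
            w0 = _snap_min_to_epoch(max(w0h, 6.0) * 60, epw)
            w1 = _snap_min_to_epoch(min(w1h, 23.5) * 60, epw)
            wear_rows.append({"participant_id": pid, "date": date,
                              "wear_start": w0 * epw / 60, "wear_end": w1 * epw / 60})

            occupied: list[tuple[int, int]] = []
            plans: list[_TripPlan] = []

            # school commutes (reserved even when not injected, so leisure
            # placement never collides with the commute slots)
            if hours is not None:
                start_ep = _snap_min_to_epoch(hours[0].hour * 60 + hours[0].minute, epw)
                end_ep = _snap_min_to_epoch(hours[1].hour * 60 + hours[1].minute, epw)
                am = (start_ep - 8 - commute_ep, start_ep - 8)
                pm = (end_ep + 8, end_ep + 8 + commute_ep)
                occupied += [am, pm]
                if cfg.school_commutes:
                    plans.append(_TripPlan(am[0], commute_ep, commute_mode, True, [], "home", "school"))
                    plans.append(_TripPlan(pm[0], commute_ep, commute_mode, True, [], "school", "home"))
            else:
                start_ep = end_ep = None

            # eligible leisure windows: wear ∩ leisure, clear of commutes
            if hours is None:
                windows = [(w0, w1)]
            else:
                windows = [(w0, max(w0, occupied[0][0] - 24)),
                           (min(w1, occupied[1][1] + 24), w1)]
                windows = [(a, b) for a, b in windows if b - a > 0]

            if di in low_days:
                pass  # low-wear days carry no leisure trips (and are invalid anyway)
            else:
                for mode in MODES:
                    if not engaged[(mode, stratum)]:
                        continue
                    rate = cfg.trip_rates[mode][1 if is_weekend else 0] * rate_mult[mode]
                    for _ in range(rng.poisson(rate)):
                        lo, hi = cfg.trip_extent_min[mode]
                        extent_ep = int(round(rng.uniform(lo, hi) * 60 / epw))
                        s = _place_interval(rng, windows, occupied, extent_ep, buffer_ep=24)
                        if s is None:
                            continue
                        plans.append(_TripPlan(s, extent_ep, mode, False,
                                               _plan_pauses(rng, extent_ep, cfg), "home", "out"))

            gps_df, accel_df, day_trips = _materialise_day(
                rng, pid, date, plans, w0, w1, cfg, th, anchors[pid],
                bad_day=(rng.random() < cfg.bad_day_p), n_per_day=n_per_day)
            gps_frames.append(gps_df)
            accel_frames.append(accel_df)
            trips_rows.extend(day_trips)

        study_cfg_anchor_rows[pid] = anchors[pid]

    gps = pd.concat(gps_frames, ignore_index=True)
    accel = pd.concat(accel_frames, ignore_index=True)
    trips = pd.DataFrame(trips_rows, columns=[
        "participant_id", "date", "start", "end", "mode", "is_school_trip", "duration_min"])

    # --- truth valid days (counted from the materialised streams) --------
    worn = accel.loc[accel["counts"] > 0, ["participant_id", "timestamp"]]
    both = worn.merge(gps[["participant_id", "timestamp"]], on=["participant_id", "timestamp"])
    both["date"] = both["timestamp"].dt.date
    cm = both.groupby(["participant_id", "date"]).size().mul(epw / 60.0)
    valid_rows = []
    for pid in pids:
        for di, date in enumerate(dates):
            minutes = float(cm.get((pid, date), 0.0))
            valid_rows.append({
                "participant_id": pid, "date": date,
                "is_weekend": date.weekday() >= 5, "is_first_day": di == 0,
                "combined_wear_minutes": minutes,
                "is_valid": di > 0 and minutes >= th.min_wear_hours * 60,
            })
    valid_days = pd.DataFrame(valid_rows)

    # --- diary ------------------------------------------------------------
    for r in trips.itertuples(index=False):
        p_report = cfg.school_trip_report_p if r.is_school_trip else cfg.report_prob[r.mode]
        if rng.random() >= p_report:
            continue
        n_entries = 1
        if (not r.is_school_trip and r.mode == "passive"
                and rng.random() < cfg.passive_split_p):
            n_entries = 2
        for _ in range(n_entries):
            diary_rows.append({"participant_id": r.participant_id, "date": r.date,
                               "mode": r.mode, "is_school_trip": r.is_school_trip})
    diary = pd.DataFrame(diary_rows, columns=["participant_id", "date", "mode", "is_school_trip"])

    study_config = StudyConfig(
        epoch_s=epw, thresholds=th, schools=schools,
        participant_school={p: school_of_class[c] for p, c in zip(pids, class_ids)},
        anchors=study_cfg_anchor_rows,
    )

    manifest = TruthManifest(
        trips=trips, valid_days=valid_days, wear_blocks=pd.DataFrame(wear_rows),
        coefficients={"env_effects": cfg.env_effects, "class_re_sd": cfg.class_re_sd},
        meta={"seed": cfg.seed, "n_participants": cfg.n_participants,
              "grid_points": {p: int((accel["participant_id"] == p).sum()) for p in pids}},
    )

    epochs = gps[["participant_id", "timestamp", "lat", "lon", "speed_kmh"]].merge(
        accel, on=["participant_id", "timestamp"], how="outer")
    epochs = epochs.sort_values(["participant_id", "timestamp"], kind="mergesort").reset_index(drop=True)

    return SimulatedStudy(epochs=epochs, gps=gps, accel=accel, diary=diary,
                          questionnaire=questionnaire, manifest=manifest,
                          study_config=study_config, config=cfg)


def _materialise_day(rng, pid, date, plans, w0, w1, cfg: SynthConfig, th: Thresholds,
                     anchors, bad_day, n_per_day):
    """Turn a day's trip plans into GPS/accelerometer epoch rows + manifest trips."""
    epw = cfg.epoch_s
    speed = np.zeros(n_per_day)
    moving = np.zeros(n_per_day, dtype=bool)
    counts = np.zeros(n_per_day)
    wear = np.zeros(n_per_day, dtype=bool)
    wear[w0:w1] = True

    # sedentary counts during wear (>=1 so the 60-min zero rule sees exactly
    # the designed non-wear blocks)
    n_wear = int(wear.sum())
    counts[wear] = np.maximum(np.round(rng.normal(150, 80, n_wear)), 1)

    if cfg.extra_nonwear_p > 0 and rng.random() < cfg.extra_nonwear_p:
        block_ep = int(round(rng.uniform(*cfg.extra_nonwear_min) * 60 / epw))
        occ = [(p.start_ep, p.start_ep + p.extent_ep) for p in plans]
        s = _place_interval(rng, [(w0, w1)], occ, block_ep, buffer_ep=4, tries=20)
        if s is not None:
            counts[s:s + block_ep] = 0
            wear[s:s + block_ep] = False

    if cfg.stationary_speed_max > 0:
        stat_noise = np.minimum(np.abs(rng.normal(0, 0.3, n_per_day)), cfg.stationary_speed_max)
        speed[:] = stat_noise

    home = anchors["home"]
    school = anchors["school"]
    lat = np.full(n_per_day, home.lat)
    lon = np.full(n_per_day, home.lon)

    day_trips = []
    for p in plans:
        idx = np.arange(p.start_ep, p.start_ep + p.extent_ep)
        mov = np.ones(p.extent_ep, dtype=bool)
        for off, plen in p.pauses:
            mov[off:off + plen] = False
        sp = np.zeros(p.extent_ep)
        sp[mov] = _draw_speeds(rng, p.mode, int(mov.sum()), cfg, th)
        if cfg.stationary_speed_max > 0:
            sp[~mov] = np.minimum(np.abs(rng.normal(0, 0.3, int((~mov).sum()))),
                                  cfg.stationary_speed_max)
        speed[idx] = sp
        moving[idx] = mov
        counts[idx] = {
            "walk": np.maximum(np.round(rng.normal(900, 200, p.extent_ep)), 1),
            "cycle": np.maximum(np.round(rng.normal(400, 150, p.extent_ep)), 1),
            "passive": np.maximum(np.round(rng.normal(60, 40, p.extent_ep)), 1),
        }[p.mode]

        # geometry: endpoints at the named anchors or out of both geofences
        if p.origin == "home" and p.dest == "school":
            a, b = (home.lat, home.lon), (school.lat, school.lon)
        elif p.origin == "school":
            a, b = (school.lat, school.lon), (home.lat, home.lon)
        else:
            a = (home.lat, home.lon)
            dist_m = float(np.sum(sp[mov]) / 3.6 * epw)
            for _try in range(20):
                bearing = rng.uniform(0, 2 * math.pi)
                blat, blon = offset_latlon(a[0], a[1], dist_m * math.sin(bearing),
                                           dist_m * math.cos(bearing))
                if haversine_m(blat, blon, school.lat, school.lon) > 2.0 * school.radius_m:
                    break
            b = (float(blat), float(blon))
        frac = np.concatenate(([0.0], np.cumsum(sp)[:-1])) / max(np.sum(sp), 1e-9)
        lat[idx] = a[0] + (b[0] - a[0]) * frac
        lon[idx] = a[1] + (b[1] - a[1]) * frac
        if p.dest in ("home", "school"):
            lat[idx[-1]], lon[idx[-1]] = b

        midnight = datetime.combine(date, time(0, 0))
        day_trips.append({
            "participant_id": pid, "date": date,
            "start": midnight + timedelta(seconds=int(p.start_ep) * epw),
            "end": midnight + timedelta(seconds=int(p.start_ep + p.extent_ep) * epw),
            "mode": p.mode, "is_school_trip": p.is_school_trip,
            "duration_min": p.extent_ep * epw / 60.0,
        })

    # GPS availability: wear window, minus dropout, minus whole-day failures
    has_fix = wear.copy()
    if bad_day:
        has_fix[:] = False
    elif cfg.gps_dropout_p > 0:
        has_fix &= rng.random(n_per_day) >= cfg.gps_dropout_p

    if cfg.positional_noise_m > 0:
        east = rng.normal(0, cfg.positional_noise_m, n_per_day)
        north = rng.normal(0, cfg.positional_noise_m, n_per_day)
        lat, lon = offset_latlon(lat, lon, east, north)

    ts0 = pd.Timestamp(datetime.combine(date, time(0, 0)))
    timestamps = ts0 + pd.to_timedelta(np.arange(n_per_day) * epw, unit="s")
    gps_df = pd.DataFrame({
        "participant_id": pid, "timestamp": timestamps[has_fix],
        "lat": np.round(lat[has_fix], 7), "lon": np.round(lon[has_fix], 7),
        "speed_kmh": np.round(speed[has_fix], 3),
    })
    accel_df = pd.DataFrame({
        "participant_id": pid, "timestamp": timestamps,
        "counts": counts.astype(int),
    })
    return gps_df, accel_df, day_trips


def inject_school_commutes(study: SimulatedStudy) -> SimulatedStudy:
    """Regenerate the study with home<->school commutes on every school day
    (morning arrival before the bell, afternoon departure after the close —
    at the early close on Wednesdays). The commute slots are reserved in
    every simulation, so injection never collides with leisure trips."""
    import copy

    cfg = copy.deepcopy(study.config)
    cfg.school_commutes = True
    return simulate_study(cfg)


def _simulate_questionnaire(rng, pids, class_ids, school_of_class, cfg: SynthConfig) -> pd.DataFrame:
    """Item-level questionnaire responses: 5-point (0-4) density frequencies,
    4-point (1-4) agreement items correlated within subscale, plus child
    age/sex/SES."""
    n = len(pids)
    rows = {"participant_id": pids,
            "class_id": class_ids,
            "school_id": [school_of_class[c] for c in class_ids]}
    # density: urban-ness latent per participant
    urban = rng.normal(0, 1, n)
    rows["density_1a"] = np.clip(np.round(3 - urban + rng.normal(0, 0.7, n)), 0, 4).astype(int)
    rows["density_1b"] = np.clip(np.round(1.5 + 0.8 * urban + rng.normal(0, 0.8, n)), 0, 4).astype(int)
    rows["density_1c"] = np.clip(np.round(1 + urban + rng.normal(0, 0.8, n)), 0, 4).astype(int)
    for sub in MEAN_SUBSCALES:
        latent = rng.normal(2.5, 0.5, n)
        for col in DEFAULT_ITEM_SETS[sub]:
            rows[col] = np.clip(np.round(latent + rng.normal(0, 0.5, n)), 1, 4).astype(int)
    rows["age"] = np.round(rng.uniform(10.0, 12.0, n), 1)
    rows["sex"] = (rng.random(n) < 0.64).astype(int)   # 1 = girl
    rows["ses"] = (rng.random(n) < 0.75).astype(int)   # 1 = high SES
    return pd.DataFrame(rows)


def _standardised_scores(questionnaire: pd.DataFrame) -> pd.DataFrame:
    """Standardised subscale scores used by the outcome linkage."""
    from .envscores import score_questionnaire

    scores = score_questionnaire(questionnaire).set_index("participant_id")
    z = pd.DataFrame(index=scores.index)
    for sub in _ENV_CENTER:
        z[sub] = (scores[sub] - _ENV_CENTER[sub]) / _ENV_SCALE[sub]
    return z


def simulate_hurdle_dataset(n_classes=25, n_per_class=20, odds_ratio=1.8,
                            exp_b=1.3, re_sd_logit=0.5, re_sd_gamma=0.5,
                            shape=2.0, intercept_logit=0.3, intercept_gamma=0.5,
                            seed=0) -> pd.DataFrame:
    """Ground-truth two-part data for recovery studies: a standard-normal
    predictor x, engagement ~ Bernoulli(logit: log(OR) x + class RE), and a
    Gamma(log link) positive amount with multiplicative effect exp_b."""
    rng = np.random.default_rng(seed)
    n = n_classes * n_per_class
    cls = np.repeat(np.arange(n_classes), n_per_class)
    x = rng.normal(0, 1, n)
    u = rng.normal(0, re_sd_logit, n_classes)
    v = rng.normal(0, re_sd_gamma, n_classes)
    eta_l = intercept_logit + np.log(odds_ratio) * x + u[cls]
    engaged = rng.random(n) < 1 / (1 + np.exp(-eta_l))
    mu = np.exp(intercept_gamma + np.log(exp_b) * x + v[cls])
    y = np.where(engaged, rng.gamma(shape, mu / shape), 0.0)
    return pd.DataFrame({"y": y, "x": x, "class_id": [f"C{c:02d}" for c in cls]})
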