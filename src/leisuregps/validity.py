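"""Concurrent validity of GPS-determined versus self-reported transport.

Pearson correlations (classified low <=0.30, moderate 0.31-0.50, high
>0.50) and paired t-tests per mode x stratum, plus GPS week-vs-weekend
contrasts and not-engaging percentages for both instruments. The paired t
is available both from raw paired vectors and from printed summary
statistics (means, SDs, r, n), which lets rows of a published comparison
table be reconstructed without the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .leisure import MODES, STRATA


@dataclass(frozen=True)
class PairedComparison:
    mode: str
    stratum: str
    n: int
    mean_gps: float
    sd_gps: float
    mean_self: float
    sd_self: float
    pearson_r: float
    r_p_value: float
    t_statistic: float
    df: int
    p_value: float
    r_class: str


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def classify_r(r: float) -> str:
    """Correlation magnitude class: low (<=0.30), moderate (0.31-0.50), high (>0.50)."""
    if not np.isfinite(r):
        raise ValueError("r must be finite")
    a = abs(r)
    if a <= 0.30:
        return "low"
    if a <= 0.50:
        return "moderate"
    return "high"


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired t-test from raw vectors: t = mean(d)/(sd(d)/sqrt(n)), df = n-1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need paired vectors with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        t = np.inf if d.mean() != 0 else 0.0
        return float(t), n - 1, 0.0 if d.mean() != 0 else 1.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def paired_t_from_summary(m1: float, sd1: float, m2: float, sd2: float,
                          r: float, n: int) -> tuple[float, int, float]:
    """Paired t from summary statistics:
    t = (m1 - m2) / sqrt((sd1^2 + sd2^2 - 2 r sd1 sd2) / n)."""
    var_d = sd1 ** 2 + sd2 ** 2 - 2.0 * r * sd1 * sd2
    if var_d <= 0:
        raise ValueError("implied difference variance is non-positive")
    t = (m1 - m2) / np.sqrt(var_d / n)
    p = 2 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def _pairwise(gps: pd.DataFrame, self_rep: pd.DataFrame, mode: str, stratum: str,
              col: str) -> pd.DataFrame:
    g = gps[(gps["mode"] == mode) & (gps["stratum"] == stratum)][["participant_id", col]]
    s = self_rep[(self_rep["mode"] == mode) & (self_rep["stratum"] == stratum)][["participant_id", col]]
    merged = g.merge(s, on="participant_id", suffixes=("_gps", "_self")).dropna()
    return merged


def compare_pair(gps: pd.DataFrame, self_rep: pd.DataFrame, mode: str, stratum: str,
                 col: str = "trips_per_day") -> PairedComparison:
    m = _pairwise(gps, self_rep, mode, stratum, col)
    x, y = m[f"{col}_gps"].to_numpy(), m[f"{col}_self"].to_numpy()
    n = x.size
    if n < 3 or x.std() == 0 or y.std() == 0:
        r, rp = float("nan"), float("nan")
    else:
        r, rp = pearson_r(x, y)
    if n >= 2:
        t, df, p = paired_t(x, y)
    else:
        t, df, p = float("nan"), max(n - 1, 0), float("nan")
    return PairedComparison(
        mode=mode, stratum=stratum, n=n,
        mean_gps=float(x.mean()) if n else float("nan"),
        sd_gps=float(x.std(ddof=1)) if n > 1 else float("nan"),
        mean_self=float(y.mean()) if n else float("nan"),
        sd_self=float(y.std(ddof=1)) if n > 1 else float("nan"),
        pearson_r=r, r_p_value=rp, t_statistic=t, df=df, p_value=p,
        r_class=classify_r(r) if np.isfinite(r) else "undefined",
    )


def compare_table(gps_outcomes: pd.DataFrame, diary_outcomes: pd.DataFrame) -> pd.DataFrame:
    """The full comparison table: GPS-vs-self per mode x stratum (trips/day),
    GPS week-vs-weekend contrasts (trips/day, min/day, min/trip), and
    not-engaging percentages for both instruments."""
    rows = []
    for mode in MODES:
        for stratum in STRATA:
            c = compare_pair(gps_outcomes, diary_outcomes, mode, stratum)
            rows.append({"comparison": "gps_vs_self", "measure": "trips_per_day",
                         **c.__dict__})
    # GPS week vs weekend, within participants
    for mode in MODES:
        for measure in ["trips_per_day", "minutes_per_day", "minutes_per_trip"]:
            wk = gps_outcomes[(gps_outcomes["mode"] == mode) & (gps_outcomes["stratum"] == "week")]
            we = gps_outcomes[(gps_outcomes["mode"] == mode) & (gps_outcomes["stratum"] == "weekend")]
            m = wk[["participant_id", measure]].merge(
                we[["participant_id", measure]], on="participant_id",
                suffixes=("_week", "_weekend")).dropna()
            n = len(m)
            if n >= 2:
                t, df, p = paired_t(m[f"{measure}_week"], m[f"{measure}_weekend"])
            else:
                t, df, p = float("nan"), max(n - 1, 0), float("nan")
            rows.append({
                "comparison": "gps_week_vs_weekend", "measure": measure, "mode": mode,
                "stratum": "both", "n": n,
                "mean_gps": m[f"{measure}_week"].mean() if n else float("nan"),
                "sd_gps": m[f"{measure}_week"].std(ddof=1) if n > 1 else float("nan"),
                "mean_self": m[f"{measure}_weekend"].mean() if n else float("nan"),
                "sd_self": m[f"{measure}_weekend"].std(ddof=1) if n > 1 else float("nan"),
                "pearson_r": float("nan"), "r_p_value": float("nan"),
                "t_statistic": t, "df": df, "p_value": p, "r_class": "undefined",
            })
    # not-engaging percentages
    for mode in MODES:
        for stratum in STRATA:
            for label, table in (("gps", gps_outcomes), ("self", diary_outcomes)):
                sub = table[(table["mode"] == mode) & (table["stratum"] == stratum)].dropna(subset=["trips_per_day"])
                n = len(sub)
                pct = 100.0 * (~sub["engaged"].astype(bool)).mean() if n else float("nan")
                rows.append({
                    "comparison": f"not_engaging_{label}", "measure": "percent",
                    "mode": mode, "stratum": stratum, "n": n,
                    "mean_gps": pct if label == "gps" else float("nan"),
                    "mean_self": pct if label == "self" else float("nan"),
                    "sd_gps": float("nan"), "sd_self": float("nan"),
                    "pearson_r": float("nan"), "r_p_value": float("nan"),
                    "t_statistic": float("nan"), "df": 0, "p_value": float("nan"),
                    "r_class": "undefined",
                })
    return pd.DataFrame(rows)
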