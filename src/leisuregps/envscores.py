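"""Parental neighborhood-environment questionnaire scoring (NEWS-Y derived).

Seven subscales: a weighted residential-density score plus six mean scores
(land use mix access, street connectivity, walking/cycling facilities,
aesthetics, traffic safety, crime safety) on a 1-4 agreement scale.

Residential density weights dwelling types by their person-density relative
to standalone single-family homes: ``q1a + 12*q1b + 25*q1c`` where the three
items (single-family homes, row houses, apartments) are frequency responses
on a 5-point none..all scale coded 0-4.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESIDENTIAL_DENSITY_WEIGHTS = (1.0, 12.0, 25.0)

MEAN_SUBSCALES = [
    "land_use_mix_access", "street_connectivity", "walk_cycle_facilities",
    "aesthetics", "traffic_safety", "crime_safety",
]
SUBSCALES = ["residential_density"] + MEAN_SUBSCALES

#: default item columns per subscale in the questionnaire CSV; the item sets
#: are configurable because instruments adapt item counts per deployment.
DEFAULT_ITEM_SETS = {
    "residential_density": ["density_1a", "density_1b", "density_1c"],
    "land_use_mix_access": [f"lum_{i}" for i in range(1, 5)],
    "street_connectivity": [f"conn_{i}" for i in range(1, 4)],
    "walk_cycle_facilities": [f"fac_{i}" for i in range(1, 5)],
    "aesthetics": [f"aes_{i}" for i in range(1, 4)],
    "traffic_safety": [f"traf_{i}" for i in range(1, 5)],
    "crime_safety": [f"crime_{i}" for i in range(1, 4)],
}

COVARIATES = ["age", "sex", "ses"]


def score_residential_density(q1a, q1b, q1c):
    """Weighted dwelling-frequency score ``q1a + 12*q1b + 25*q1c``.

    Responses are 5-point frequency codes 0 ("none") through 4 ("all").
    """
    a, b, c = (np.asarray(q, dtype=float) for q in (q1a, q1b, q1c))
    for q in (a, b, c):
        vals = q[~np.isnan(q)]
        if ((vals < 0) | (vals > 4)).any():
            raise ValueError("residential-density responses must be coded 0-4")
    w1, w2, w3 = RESIDENTIAL_DENSITY_WEIGHTS
    return w1 * a + w2 * b + w3 * c


def score_mean_subscale(items, min_fraction: float = 0.5):
    """Mean of 4-point agreement items (coded 1-4), rows x items.

    Missing items are skipped when at least ``min_fraction`` of the items are
    present; otherwise the subscale is undefined (NaN, logged).
    """
    x = np.atleast_2d(np.asarray(items, dtype=float))
    vals = x[~np.isnan(x)]
    if ((vals < 1) | (vals > 4)).any():
        raise ValueError("agreement items must be coded 1-4")
    n_present = (~np.isnan(x)).sum(axis=1)
    enough = n_present >= max(1, int(np.ceil(min_fraction * x.shape[1])))
    if (~enough).any():
        logger.warning("%d respondents below the %d%%-present rule; subscale set missing",
                       int((~enough).sum()), int(100 * min_fraction))
    with np.errstate(invalid="ignore"):
        means = np.where(enough & (n_present > 0), np.nanmean(np.where(np.isnan(x), np.nan, x), axis=1), np.nan)
    return means if means.size > 1 else float(means[0])


def cronbach_alpha(items) -> float:
    """Cronbach's alpha, k/(k-1) * (1 - sum(item variances)/var(total))."""
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need >=2 respondents and >=2 items")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return k / (k - 1) * (1.0 - item_var.sum() / total_var)


def score_questionnaire(questionnaire: pd.DataFrame,
                        item_sets: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Score every respondent: 7 subscale columns + age/sex/SES covariates."""
    item_sets = item_sets or DEFAULT_ITEM_SETS
    out = pd.DataFrame({"participant_id": questionnaire["participant_id"].astype(str)})
    dens_items = item_sets["residential_density"]
    out["residential_density"] = score_residential_density(
        *(questionnaire[c] for c in dens_items)
    )
    for sub in MEAN_SUBSCALES:
        out[sub] = score_mean_subscale(questionnaire[item_sets[sub]].to_numpy())
    for cov in COVARIATES + ["class_id", "school_id"]:
        if cov in questionnaire.columns:
            out[cov] = questionnaire[cov].to_numpy()
    return out


def internal_consistency(questionnaire: pd.DataFrame,
                         item_sets: dict[str, list[str]] | None = None) -> pd.Series:
    """Cronbach's alpha per multi-item subscale."""
    item_sets = item_sets or DEFAULT_ITEM_SETS
    alphas = {}
    for sub, cols in item_sets.items():
        if len(cols) >= 2:
            alphas[sub] = cronbach_alpha(questionnaire[cols].dropna().to_numpy())
    return pd.Series(alphas, name="cronbach_alpha")
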