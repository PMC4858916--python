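"""Association models: recovery, family selection, hurdle consistency."""

import numpy as np
import pandas as pd
import pytest

from leisuregps.assoc import (
    ModelSpec, build_model_frame, fit_association_model, fit_gamma_log, fit_gaussian,
    fit_hurdle, select_family_by_aic, RESULT_COLUMNS,
)
from leisuregps.envscores import SUBSCALES


def regression_cohort(n_classes=25, n_per_class=8, seed=0, beta_aesthetics=4.0,
                      re_sd=0.5, resid_sd=2.0):
    """Participant-level frame with the full adjuster set and a known
    aesthetics effect on a Gaussian outcome."""
    rng = np.random.default_rng(seed)
    n = n_classes * n_per_class
    cls = np.repeat([f"C{c:02d}" for c in range(n_classes)], n_per_class)
    d = pd.DataFrame({
        "participant_id": [f"P{i:03d}" for i in range(n)],
        "class_id": cls,
        "school_id": np.where(np.arange(n) % 2 == 0, "S1", "S2"),
        "age": rng.uniform(10, 12, n),
        "sex": rng.integers(0, 2, n),
        "ses": rng.integers(0, 2, n),
        "wear_min": rng.normal(700, 50, n),
    })
    for sub in SUBSCALES:
        d[sub] = rng.normal(2.5, 0.5, n) if sub != "residential_density" else rng.normal(60, 20, n)
    u = dict(zip(sorted(set(cls)), rng.normal(0, re_sd, n_classes)))
    d["y"] = (2.0 + beta_aesthetics * d["aesthetics"]
              + np.array([u[c] for c in cls]) + rng.normal(0, resid_sd, n))
    return d


FORMULA = ModelSpec("walk", "week", "trips_per_day", "gaussian_identity").formula("y")


class TestGaussian:
    def test_known_effect_recovered_within_ci(self):
        d = regression_cohort(seed=1)
        res = fit_gaussian(FORMULA, d, "class_id")
        t = res.fe_table().set_index("predictor")
        row = t.loc["aesthetics"]
        assert row["ci_low"] <= 4.0 <= row["ci_high"]
        assert row["estimate"] == pytest.approx(4.0, abs=0.6)

    def test_zero_re_variance_truth_close_to_ols(self):
        import statsmodels.api as sm
        import patsy

        d = regression_cohort(seed=2, re_sd=0.0)
        res = fit_gaussian(FORMULA, d, "class_id")
        y, X = patsy.dmatrices(FORMULA, d, return_type="dataframe")
        ols = sm.OLS(y, X).fit()
        assert np.allclose(res.params, ols.params, atol=0.05)

    def test_constant_predictor_no_crash_ci_covers_zero(self):
        d = regression_cohort(seed=3)
        d["aesthetics"] = 0.0
        d["y"] = 2.0 + np.random.default_rng(3).normal(0, 1, len(d))
        res = fit_gaussian(FORMULA, d, "class_id")
        row = res.fe_table().set_index("predictor").loc["aesthetics"]
        assert row["ci_low"] <= 0.0 <= row["ci_high"] or row["estimate"] == 0.0


class TestGammaAndHurdle:
    @staticmethod
    def gamma_cohort(seed=4, exp_b=1.5, zeros=False):
        rng = np.random.default_rng(seed)
        d = regression_cohort(seed=seed, beta_aesthetics=0.0)
        mu = np.exp(0.5 + np.log(exp_b) * (d["aesthetics"] - 2.5))
        d["y"] = rng.gamma(2.0, mu / 2.0)
        if zeros:
            d.loc[rng.random(len(d)) < 0.3, "y"] = 0.0
        return d

    def test_multiplicative_effect_recovered(self):
        d = self.gamma_cohort()
        res = fit_gamma_log(FORMULA, d, "class_id")
        t = res.fe_table().set_index("predictor").loc["aesthetics"]
        assert t["ci_low"] <= 1.5 <= t["ci_high"]

    def test_null_predictor_ci_covers_one(self):
        d = self.gamma_cohort(exp_b=1.0, seed=5)
        res = fit_gamma_log(FORMULA, d, "class_id")
        t = res.fe_table().set_index("predictor").loc["crime_safety"]
        assert t["ci_low"] <= 1.0 <= t["ci_high"]

    def test_zeros_directed_to_hurdle(self):
        d = self.gamma_cohort(zeros=True)
        with pytest.raises(ValueError, match="hurdle"):
            fit_gamma_log(FORMULA, d, "class_id")

    def test_hurdle_without_zeros_reduces_to_gamma(self):
        d = self.gamma_cohort()
        h = fit_hurdle(FORMULA, d, "class_id")
        assert h.skipped == "logit" and h.logit is None
        g = fit_gamma_log(FORMULA, d, "class_id")
        assert np.allclose(h.positive.params, g.params, atol=1e-5)

    def test_hurdle_two_parts_reported(self):
        d = self.gamma_cohort(zeros=True)
        h = fit_hurdle(FORMULA, d, "class_id")
        frame = h.to_frame()
        assert set(frame["part"]) == {"logit", "positive"}
        assert set(frame["scale"]) == {"OR", "exp(b)"}
        assert h.n_positive < h.n_total
        assert (frame["ci_low"] <= frame["estimate"]).all()
        assert (frame["estimate"] <= frame["ci_high"]).all()
        assert (frame["estimate"] > 0).all()


class TestModelSelection:
    def test_gaussian_truth_prefers_gaussian_aic(self):
        d = regression_cohort(seed=6, beta_aesthetics=0.0)
        d["y"] = d["y"] - d["y"].min() + 1.0  # keep Gamma applicable
        gauss = fit_gaussian(FORMULA, d, "class_id")
        gamma = fit_gamma_log(FORMULA, d, "class_id")
        assert select_family_by_aic([gauss, gamma]) is gauss

    def test_identical_candidates_tie_break_to_first(self):
        d = regression_cohort(seed=7)
        a = fit_gaussian(FORMULA, d, "class_id")
        b = fit_gaussian(FORMULA, d, "class_id")
        assert select_family_by_aic([a, b]) is a

    def test_single_candidate_returned(self):
        d = regression_cohort(seed=8)
        a = fit_gaussian(FORMULA, d, "class_id")
        assert select_family_by_aic([a]) is a

    def test_covariate_set_must_be_complete(self):
        with pytest.raises(ValueError):
            ModelSpec("walk", "week", "trips_per_day", "gaussian_identity",
                      covariates=("age", "sex"))


def test_tidy_table_from_spec_driver():
    d = TestGammaAndHurdle.gamma_cohort(seed=9, zeros=True)
    outcomes = pd.DataFrame({
        "participant_id": d["participant_id"], "stratum": "weekend", "mode": "walk",
        "trips_per_day": d["y"], "minutes_per_day": d["y"] * 6, "engaged": d["y"] > 0,
    })
    scores = d.drop(columns=["y", "wear_min"])
    weardays = pd.DataFrame({
        "participant_id": np.repeat(d["participant_id"], 2),
        "date": [dt for _ in range(len(d)) for dt in ("2014-01-11", "2014-01-12")],
        "combined_wear_minutes": 700.0, "is_weekend": True,
        "is_valid": True, "is_first_day": False,
    })
    spec = ModelSpec("walk", "weekend", "trips_per_day", "hurdle")
    frame = build_model_frame(spec, outcomes, scores, weardays)
    assert "wear_min" in frame.columns and len(frame) == len(d)
    table = fit_association_model(spec, frame)
    assert list(table.columns) == RESULT_COLUMNS
    assert set(table["part"]) == {"logit", "positive"}
    assert (table["outcome"] == "walk_weekend_trips_per_day").all()
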