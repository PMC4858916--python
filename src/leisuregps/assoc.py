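"""Association models between neighborhood-environment scores and
GPS-determined leisure-time transport outcomes.

Three model types, all with a school-class random intercept and all
adjusted for age, sex, SES, school and wear time:

* Gaussian identity linear mixed model (ML) for approximately normal
  outcomes — reports beta with 95% CI;
* Gamma log-link GLMM for positive skewed outcomes — reports exp(b);
* a two-part hurdle GLMM for zero-heavy outcomes: a mixed logistic model
  for any engagement (OR) over everyone, and a mixed Gamma-log model for
  the amount among engagers (exp(b)); both parts are fitted by adaptive
  Gauss-Hermite quadrature with 25 points.

Family choice between converged candidates on the same data can be made
by AIC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy

from .envscores import SUBSCALES
from .glmm import MixedGammaLog, MixedGLMResults, MixedLogit

logger = logging.getLogger(__name__)

ADJUSTERS = ["age", "sex", "ses", "school", "wear_time"]

RESULT_COLUMNS = [
    "outcome", "part", "predictor", "estimate", "ci_low", "ci_high", "scale", "n", "converged",
]


@dataclass(frozen=True)
class ModelSpec:
    """One association model: which outcome, which family, which predictors."""

    mode: str
    stratum: str
    measure: str                      # trips_per_day | minutes_per_day
    family: str                       # gaussian_identity | gamma_log | hurdle
    predictors: tuple = tuple(SUBSCALES)
    covariates: tuple = tuple(ADJUSTERS)

    def __post_init__(self):
        missing = set(ADJUSTERS) - set(self.covariates)
        if missing:
            raise ValueError(f"covariate set must include all adjusters; missing {sorted(missing)}")

    @property
    def outcome_label(self) -> str:
        return f"{self.mode}_{self.stratum}_{self.measure}"

    def formula(self, lhs: str = "y") -> str:
        rhs = " + ".join(list(self.predictors) + ["age", "C(sex)", "C(ses)", "C(school_id)", "wear_min"])
        return f"{lhs} ~ {rhs}"


# ---------------------------------------------------------------------------
# Gaussian identity (statsmodels MixedLM, ML)


@dataclass
class GaussianMixedResults:
    """Linear mixed model results with the same reporting surface as the
    AGQ models (beta scale, not exponentiated)."""

    params: np.ndarray
    bse_: np.ndarray
    exog_names: list
    llf: float
    k_params: int
    converged: bool
    re_var: float
    scale_label: str = "beta"

    @property
    def aic(self):
        return 2.0 * self.k_params - 2.0 * self.llf

    def fe_table(self, alpha=0.05) -> pd.DataFrame:
        z = 1.959963984540054
        return pd.DataFrame({
            "predictor": self.exog_names,
            "estimate": self.params,
            "ci_low": self.params - z * self.bse_,
            "ci_high": self.params + z * self.bse_,
            "scale": self.scale_label,
        })

    def summary(self) -> str:
        t = self.fe_table()
        head = (f"Gaussian identity mixed model (ML)  llf: {self.llf:.4f}  "
                f"AIC: {self.aic:.4f}  RE var: {self.re_var:.4f}  converged: {self.converged}")
        return head + "\n" + t.to_string(index=False)


def fit_gaussian(formula: str, data: pd.DataFrame, groups: str) -> GaussianMixedResults:
    """Gaussian identity linear mixed model (class random intercept, ML).

    Falls back to ordinary least squares with a warning when the
    random-effect variance estimate is singular.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    grp = data.loc[X.index, groups]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y.to_numpy().ravel(), X.to_numpy(), groups=np.asarray(grp))
            res = model.fit(reml=False, method="lbfgs")
        re_var = float(res.cov_re.iloc[0, 0])
        singular = not res.converged or not np.isfinite(re_var)
    except Exception:
        singular = True
    if singular:
        logger.warning("singular random-effect variance; falling back to fixed-effects OLS")
        ols = sm.OLS(y.to_numpy().ravel(), X.to_numpy()).fit()
        return GaussianMixedResults(
            params=np.asarray(ols.params), bse_=np.asarray(ols.bse),
            exog_names=list(X.columns), llf=float(ols.llf),
            k_params=X.shape[1] + 1, converged=True, re_var=0.0,
        )
    k = X.shape[1] + 2  # fixed effects + RE variance + residual variance
    return GaussianMixedResults(
        params=np.asarray(res.fe_params), bse_=np.asarray(res.bse_fe),
        exog_names=list(X.columns), llf=float(res.llf), k_params=k,
        converged=bool(res.converged), re_var=re_var,
    )


# ---------------------------------------------------------------------------
# Gamma log and hurdle (AGQ GLMMs)


def fit_gamma_log(formula: str, data: pd.DataFrame, groups: str, nagq: int = 25,
                  **fit_kw) -> MixedGLMResults:
    """Gamma GLMM with log link and class random intercept (AGQ)."""
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    yv = y.to_numpy().ravel()
    if (yv <= 0).any():
        raise ValueError("Gamma-log requires strictly positive outcomes; "
                         "zeros present — fit the hurdle model instead")
    model = MixedGammaLog(yv, X.to_numpy(), np.asarray(data.loc[X.index, groups]),
                          exog_names=list(X.columns))
    return model.fit(nagq=nagq, **fit_kw)


@dataclass
class HurdleResults:
    """Two-part hurdle fit: mixed logit (any engagement, OR) over everyone
    and mixed Gamma-log (amount among engagers, exp(b))."""

    logit: MixedGLMResults | None
    positive: MixedGLMResults | None
    n_total: int
    n_positive: int
    skipped: str | None = None  # 'logit' / 'positive' when degenerate

    @property
    def converged(self) -> bool:
        parts = [r for r in (self.logit, self.positive) if r is not None]
        return bool(parts) and all(r.converged for r in parts)

    @property
    def aic(self) -> float:
        return sum(r.aic for r in (self.logit, self.positive) if r is not None)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for part, res in (("logit", self.logit), ("positive", self.positive)):
            if res is None:
                continue
            t = res.fe_table()
            t.insert(0, "part", part)
            t["n"] = self.n_total if part == "logit" else self.n_positive
            t["converged"] = res.converged
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        out = [f"Hurdle GLMM  n={self.n_total} ({self.n_positive} positive)"]
        if self.skipped:
            out.append(f"degenerate outcome: {self.skipped} part skipped")
        if self.logit is not None:
            out += ["-- part 1: any engagement (logit) --", self.logit.summary()]
        if self.positive is not None:
            out += ["-- part 2: amount among engagers (Gamma log) --", self.positive.summary()]
        return "\n".join(out)


class HurdleModel:
    """Two-part mixed hurdle model for a non-negative zero-heavy outcome.

    Part 1 is a mixed logistic model on the any-engagement indicator over
    all rows; part 2 a mixed Gamma-log model on the positive subset. Both
    carry a class-level random intercept and are fitted by adaptive
    Gauss-Hermite quadrature.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        if (self.endog < 0).any():
            raise ValueError("hurdle outcome must be non-negative")
        self.exog = np.asarray(exog, dtype=float)
        self.groups = np.asarray(groups)
        self.exog_names = exog_names

    @classmethod
    def from_formula(cls, formula, data, groups):
        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        return cls(y.to_numpy().ravel(), X.to_numpy(),
                   np.asarray(data.loc[X.index, groups]), exog_names=list(X.columns))

    def fit(self, nagq: int = 25, **fit_kw) -> HurdleResults:
        pos = self.endog > 0
        n_total, n_pos = self.endog.size, int(pos.sum())
        skipped = None
        logit_res = None
        if pos.all() or not pos.any():
            skipped = "logit"
            logger.warning("hurdle: outcome has %s zeros; logit part skipped",
                           "no" if pos.all() else "only")
        else:
            logit_res = MixedLogit(pos.astype(float), self.exog, self.groups,
                                   exog_names=self.exog_names).fit(nagq=nagq, **fit_kw)
        positive_res = None
        if not pos.any():
            skipped = "positive"
            logger.warning("hurdle: all-zero outcome; positive part skipped")
        else:
            positive_res = MixedGammaLog(self.endog[pos], self.exog[pos],
                                         self.groups[pos],
                                         exog_names=self.exog_names).fit(nagq=nagq, **fit_kw)
        return HurdleResults(logit_res, positive_res, n_total, n_pos, skipped)


def fit_hurdle(formula: str, data: pd.DataFrame, groups: str, nagq: int = 25,
               **fit_kw) -> HurdleResults:
    return HurdleModel.from_formula(formula, data, groups).fit(nagq=nagq, **fit_kw)


def select_family_by_aic(fits: list) -> object:
    """The converged candidate with minimal AIC (stable order tie-break)."""
    converged = [f for f in fits if getattr(f, "converged", False)]
    dropped = len(fits) - len(converged)
    if dropped:
        logger.warning("select_family_by_aic: excluded %d non-converged candidates", dropped)
    if not converged:
        raise ValueError("no converged candidate fits")
    best = converged[0]
    for f in converged[1:]:
        if f.aic < best.aic:
            best = f
    return best


# ---------------------------------------------------------------------------
# Table-level driver


def default_model_specs() -> list[ModelSpec]:
    """The analysis grid: weekday walking is Gaussian; other weekday outcomes
    Gamma-log; weekend outcomes (zero-heavy) hurdle."""
    specs = []
    for measure in ("trips_per_day", "minutes_per_day"):
        specs.append(ModelSpec("walk", "week", measure, "gaussian_identity"))
        specs.append(ModelSpec("cycle", "week", measure, "gamma_log"))
        specs.append(ModelSpec("passive", "week", measure, "gamma_log"))
        for mode in ("walk", "cycle", "passive"):
            specs.append(ModelSpec(mode, "weekend", measure, "hurdle"))
    return specs


def build_model_frame(spec: ModelSpec, outcomes: pd.DataFrame, scores: pd.DataFrame,
                      weardays: pd.DataFrame) -> pd.DataFrame:
    """Assemble one analysis frame: outcome y, 7 subscales, adjusters,
    class grouping. Wear time enters as mean combined minutes/day over the
    participant's valid days."""
    sub = outcomes[(outcomes["mode"] == spec.mode) & (outcomes["stratum"] == spec.stratum)]
    df = sub[["participant_id", spec.measure]].rename(columns={spec.measure: "y"})
    wear = (
        weardays[weardays["is_valid"]]
        .groupby("participant_id", observed=True)["combined_wear_minutes"]
        .mean()
        .rename("wear_min")
        .reset_index()
    )
    df = df.merge(scores, on="participant_id").merge(wear, on="participant_id")
    return df.dropna(subset=["y"] + list(spec.predictors)).reset_index(drop=True)


def fit_association_model(spec: ModelSpec, data: pd.DataFrame, nagq: int = 25,
                          groups: str = "class_id") -> pd.DataFrame:
    """Fit one spec and return tidy rows (outcome, part, predictor, estimate, CI...)."""
    formula = spec.formula("y")
    n = len(data)
    if spec.family == "gaussian_identity":
        res = fit_gaussian(formula, data, groups)
        table = res.fe_table()
        table.insert(0, "part", "single")
        table["n"] = n
        table["converged"] = res.converged
    elif spec.family == "gamma_log":
        if (data["y"] <= 0).any():
            logger.warning("%s: zeros present; fitting hurdle instead of Gamma-log",
                           spec.outcome_label)
            table = fit_hurdle(formula, data, groups, nagq=nagq).to_frame()
        else:
            res = fit_gamma_log(formula, data, groups, nagq=nagq)
            table = res.fe_table()
            table.insert(0, "part", "single")
            table["n"] = n
            table["converged"] = res.converged
    elif spec.family == "hurdle":
        table = fit_hurdle(formula, data, groups, nagq=nagq).to_frame()
    else:
        raise ValueError(f"unknown family {spec.family!r}")
    table.insert(0, "outcome", spec.outcome_label)
    return table[RESULT_COLUMNS]


def fit_association_models(outcomes: pd.DataFrame, scores: pd.DataFrame,
                           weardays: pd.DataFrame, specs: list[ModelSpec] | None = None,
                           nagq: int = 25) -> pd.DataFrame:
    """Fit the whole analysis grid and return one tidy results table."""
    specs = specs or default_model_specs()
    frames = []
    for spec in specs:
        data = build_model_frame(spec, outcomes, scores, weardays)
        if data.empty or data["y"].count() < 10:
            logger.warning("%s: too few observations; skipped", spec.outcome_label)
            continue
        frames.append(fit_association_model(spec, data, nagq=nagq))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=RESULT_COLUMNS)
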