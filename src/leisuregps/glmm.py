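"""Random-intercept GLMMs fitted by adaptive Gauss-Hermite quadrature.

Implements the two mixed-model families needed for the association
analyses that ordinary linear mixed-model software does not cover here:
a mixed logistic model (any-engagement) and a mixed Gamma model with log
link (amount among engagers), each with a single Gaussian random intercept
per cluster (school class).

The marginal log-likelihood integrates the random intercept out per
cluster,

    L_i = int prod_j f(y_ij | x_ij'b + u) phi(u; 0, s^2) du,

by adaptive Gauss-Hermite quadrature: the integrand's mode u_i* is found by
Newton's method (the integrand is log-concave in u for both families), the
quadrature nodes are recentred at u_i* and rescaled by the curvature there,
and the integral is accumulated on the log scale. 25 quadrature points are
the default; refining the rule leaves well-conditioned fits unchanged to
high accuracy.

Maximisation is quasi-Newton (L-BFGS-B) over (b, log s[, log shape]) with
standard errors from the numerically differentiated Hessian of the marginal
log-likelihood (Wald intervals, exponentiated for OR / exp(b) scales).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special
from scipy.special import gammaln, logsumexp

_LOG_2PI = np.log(2.0 * np.pi)


def _numeric_hessian(f, x, step=1e-4):
    """Central-difference Hessian of scalar f at x (symmetrised)."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


class _AGQMixedGLM:
    """Shared machinery for one-random-intercept GLMMs fitted by AGQ."""

    #: names of auxiliary (non-beta, non-sd) parameters
    aux_names: tuple[str, ...] = ()

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        codes, uniques = pd.factorize(np.asarray(groups), sort=True)
        self.group_codes = codes
        self.group_labels = uniques
        self.n_groups = len(uniques)
        self.nobs = self.endog.size
        if exog_names is None:
            exog_names = [f"x{i}" for i in range(self.exog.shape[1])]
        self.exog_names = list(exog_names)
        self.k_fe = self.exog.shape[1]
        self._validate()

    @classmethod
    def from_formula(cls, formula, data, groups):
        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        grp = data.loc[X.index, groups] if isinstance(groups, str) else groups
        return cls(y.to_numpy().ravel(), X.to_numpy(), np.asarray(grp),
                   exog_names=list(X.columns))

    # family hooks -------------------------------------------------------
    def _validate(self):
        pass

    def _ll_obs(self, eta, aux):
        raise NotImplementedError

    def _dll_deta(self, eta, aux):
        raise NotImplementedError

    def _d2ll_deta2(self, eta, aux):
        raise NotImplementedError

    def _start_aux(self):
        return np.empty(0)

    # standardisation ----------------------------------------------------
    def _standardiser(self):
        """Center/scale transform for the fixed-effect columns (fitting on
        standardised predictors conditions the optimisation; estimates and
        covariance are mapped back to the original scale afterwards).

        Returns (Z, A) where Z is the standardised design and A the linear
        map params_original = A @ params_standardised.
        """
        X = self.exog
        sd = X.std(axis=0)
        const_cols = np.flatnonzero(sd == 0)
        k_all = self.k_fe + 1 + len(self.aux_names)
        A = np.eye(k_all)
        if const_cols.size == 0:
            return X, A  # no intercept to absorb centering; fit as-is
        c = const_cols[0]
        v = X[0, c] if X[0, c] != 0 else 1.0
        m = X.mean(axis=0)
        Z = X.copy()
        for j in range(self.k_fe):
            if j in const_cols or sd[j] == 0:
                continue
            Z[:, j] = (X[:, j] - m[j]) / sd[j]
            A[j, j] = 1.0 / sd[j]
            A[c, j] = -m[j] / (sd[j] * v)
        return Z, A

    # likelihood ---------------------------------------------------------
    def _split(self, params):
        p = self.k_fe
        beta = params[:p]
        log_sd = params[p]
        aux = params[p + 1:]
        return beta, log_sd, aux

    def _find_modes(self, eta, sd, aux, tol=1e-11, maxiter=100):
        """Newton mode + curvature of the per-cluster integrand in u."""
        gi = self.group_codes
        u = np.zeros(self.n_groups)
        inv_var = 1.0 / sd ** 2
        for _ in range(maxiter):
            e = eta + u[gi]
            g1 = np.bincount(gi, weights=self._dll_deta(e, aux), minlength=self.n_groups) - u * inv_var
            g2 = np.bincount(gi, weights=self._d2ll_deta2(e, aux), minlength=self.n_groups) - inv_var
            step = g1 / g2
            step = np.clip(step, -10.0, 10.0)
            u = u - step
            if np.max(np.abs(step)) < tol:
                break
        e = eta + u[gi]
        curv = -(np.bincount(gi, weights=self._d2ll_deta2(e, aux), minlength=self.n_groups) - inv_var)
        return u, curv

    def loglike(self, params, nagq=25):
        """Marginal log-likelihood by adaptive Gauss-Hermite quadrature."""
        beta, log_sd, aux = self._split(params)
        eta = self.exog @ beta
        sd = np.exp(log_sd)
        gi = self.group_codes
        u_hat, curv = self._find_modes(eta, sd, aux)
        tau = 1.0 / np.sqrt(curv)
        z, w = hermgauss(nagq)
        log_w = np.log(w)
        # g(u) at each recentred node, per cluster
        terms = np.empty((self.n_groups, nagq))
        for k in range(nagq):
            u_k = u_hat + np.sqrt(2.0) * tau * z[k]
            e = eta + u_k[gi]
            ll_clu = np.bincount(gi, weights=self._ll_obs(e, aux), minlength=self.n_groups)
            log_phi = -0.5 * (u_k / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI
            terms[:, k] = log_w[k] + z[k] ** 2 + ll_clu + log_phi
        log_L = logsumexp(terms, axis=1) + 0.5 * np.log(2.0) + np.log(tau)
        return float(np.sum(log_L))

    def loglike_fixed(self, beta_aux):
        """Log-likelihood with the random-effect variance fixed to zero
        (collapses to the ordinary GLM)."""
        beta = beta_aux[: self.k_fe]
        aux = beta_aux[self.k_fe:]
        return float(np.sum(self._ll_obs(self.exog @ beta, aux)))

    def _start_params(self):
        raise NotImplementedError

    def _clone_with_exog(self, Z):
        new = object.__new__(type(self))
        new.__dict__ = {**self.__dict__, "exog": Z}
        return new

    def fit(self, nagq=25, start_params=None, fix_re_sd=None, restarts=5,
            seed=0, gtol=1e-9):
        """Maximise the marginal likelihood.

        fix_re_sd=0 fits the ordinary GLM (no random effect); a positive
        value profiles the likelihood at that random-intercept SD. On a
        failed or suspicious convergence, up to ``restarts`` jittered
        restarts are tried and the best likelihood kept. Fitting happens on
        internally standardised predictors; results are reported on the
        original scale.
        """
        Z, A = self._standardiser()
        inner = self._clone_with_exog(Z)
        k = self.k_fe
        Ab = A[:k, :k]
        if start_params is not None:
            start_params = np.asarray(start_params, dtype=float).copy()
            start_params[:k] = np.linalg.solve(Ab, start_params[:k])
        raw = inner._fit_raw(nagq=nagq, start_params=start_params,
                             fix_re_sd=fix_re_sd, restarts=restarts, seed=seed, gtol=gtol)
        params = raw.params.copy()
        params[:k] = Ab @ raw.params[:k]
        cov = raw.cov_params.copy()
        cov[:k, :k] = Ab @ raw.cov_params[:k, :k] @ Ab.T
        cov[:k, k:] = Ab @ raw.cov_params[:k, k:]
        cov[k:, :k] = cov[:k, k:].T
        return MixedGLMResults(self, params, cov, raw.llf, raw.nagq, raw.converged)

    def _fit_raw(self, nagq=25, start_params=None, fix_re_sd=None, restarts=5,
                 seed=0, gtol=1e-9):
        if fix_re_sd is not None and fix_re_sd == 0:
            x0 = start_params if start_params is not None else np.concatenate(
                [self._start_params(), self._start_aux()])
            res = optimize.minimize(lambda p: -self.loglike_fixed(p), x0,
                                    method="L-BFGS-B", jac="3-point",
                                    options={"maxiter": 500, "gtol": gtol, "ftol": 1e-13})
            params = np.concatenate([res.x[: self.k_fe], [-np.inf], res.x[self.k_fe:]])
            H = _numeric_hessian(lambda p: -self.loglike_fixed(p), res.x)
            cov = _safe_inv(H)
            full_cov = np.full((params.size, params.size), np.nan)
            idx = [i for i in range(params.size) if i != self.k_fe]
            full_cov[np.ix_(idx, idx)] = cov
            return MixedGLMResults(self, params, full_cov, -res.fun, nagq=0,
                                   converged=bool(res.success))

        if fix_re_sd is not None:
            fixed_log_sd = np.log(fix_re_sd)

            def pack(p):
                return np.concatenate([p[: self.k_fe], [fixed_log_sd], p[self.k_fe:]])

            x0 = np.concatenate([self._start_params(), self._start_aux()])
            res = optimize.minimize(lambda p: -self.loglike(pack(p), nagq), x0,
                                    method="L-BFGS-B", jac="3-point",
                                    options={"maxiter": 500, "gtol": gtol, "ftol": 1e-13})
            params = pack(res.x)
            H = _numeric_hessian(lambda p: -self.loglike(pack(p), nagq), res.x)
            cov = _safe_inv(H)
            full_cov = np.full((params.size, params.size), np.nan)
            idx = [i for i in range(params.size) if i != self.k_fe]
            full_cov[np.ix_(idx, idx)] = cov
            return MixedGLMResults(self, params, full_cov, -res.fun, nagq,
                                   converged=bool(res.success))

        if start_params is None:
            start_params = np.concatenate([self._start_params(), [np.log(0.5)], self._start_aux()])
        neg = lambda p: -self.loglike(p, nagq)
        best = None
        rng = np.random.default_rng(seed)
        x0 = np.asarray(start_params, dtype=float)
        for attempt in range(restarts + 1):
            res = optimize.minimize(neg, x0, method="L-BFGS-B", jac="3-point",
                                    options={"maxiter": 1000, "gtol": gtol, "ftol": 1e-13})
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            if res.success:
                break
            x0 = np.asarray(start_params) + rng.normal(scale=0.2, size=len(start_params))
        H = _numeric_hessian(neg, best.x)
        cov = _safe_inv(H)
        return MixedGLMResults(self, best.x, cov, -best.fun, nagq,
                               converged=bool(best.success))


def _safe_inv(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


class MixedLogit(_AGQMixedGLM):
    """Mixed logistic regression (Bernoulli, logit link) with one Gaussian
    random intercept per cluster, fitted by adaptive Gauss-Hermite
    quadrature. Fixed effects are reported as odds ratios."""

    def _validate(self):
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("binary endog required (0/1)")

    def _ll_obs(self, eta, aux):
        return self.endog * eta - np.logaddexp(0.0, eta)

    def _dll_deta(self, eta, aux):
        return self.endog - special.expit(eta)

    def _d2ll_deta2(self, eta, aux):
        p = special.expit(eta)
        return -p * (1.0 - p)

    def _start_params(self):
        import statsmodels.api as sm

        try:
            fit = sm.GLM(self.endog, self.exog, family=sm.families.Binomial()).fit()
            return np.asarray(fit.params, dtype=float)
        except Exception:
            return np.zeros(self.k_fe)


class MixedGammaLog(_AGQMixedGLM):
    """Mixed Gamma regression (log link) with one Gaussian random intercept
    per cluster, fitted by adaptive Gauss-Hermite quadrature; the shape is
    estimated jointly by maximum likelihood. Fixed effects are reported as
    exp(b) — the proportional change in the outcome per unit predictor."""

    aux_names = ("log_shape",)

    def _validate(self):
        if (self.endog <= 0).any():
            raise ValueError("Gamma-log outcomes must be strictly positive; "
                             "use the hurdle model when zeros are present")

    def _ll_obs(self, eta, aux):
        k = np.exp(aux[0])
        y = self.endog
        return k * np.log(k) - k * eta + (k - 1.0) * np.log(y) - k * y * np.exp(-eta) - gammaln(k)

    def _dll_deta(self, eta, aux):
        k = np.exp(aux[0])
        return k * (self.endog * np.exp(-eta) - 1.0)

    def _d2ll_deta2(self, eta, aux):
        k = np.exp(aux[0])
        return -k * self.endog * np.exp(-eta)

    def _start_params(self):
        import statsmodels.api as sm

        try:
            fit = sm.GLM(self.endog, self.exog,
                         family=sm.families.Gamma(link=sm.families.links.Log())).fit()
            return np.asarray(fit.params, dtype=float)
        except Exception:
            beta = np.zeros(self.k_fe)
            beta[0] = np.log(self.endog.mean())
            return beta

    def _start_aux(self):
        mu = self.endog.mean()
        cv2 = self.endog.var() / mu ** 2 if mu > 0 else 1.0
        return np.array([np.log(max(1.0 / max(cv2, 1e-3), 0.1))])


@dataclass
class MixedGLMResults:
    """Results of an AGQ-fitted mixed GLM: estimates, Wald uncertainty,
    information criteria and a printable summary."""

    model: _AGQMixedGLM
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    nagq: int
    converged: bool
    scale_label: str = field(init=False)

    def __post_init__(self):
        self.scale_label = "OR" if isinstance(self.model, MixedLogit) else "exp(b)"

    @property
    def param_names(self):
        return self.model.exog_names + ["log_re_sd"] + list(self.model.aux_names)

    @property
    def fe_params(self):
        return self.params[: self.model.k_fe]

    @property
    def re_sd(self):
        return float(np.exp(self.params[self.model.k_fe]))

    @property
    def bse(self):
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov_params))

    @property
    def k_params(self):
        # -inf log-sd marks a model without a random effect
        return self.params.size - (1 if not np.isfinite(self.params[self.model.k_fe]) else 0)

    @property
    def aic(self):
        return 2.0 * self.k_params - 2.0 * self.llf

    def conf_int(self, alpha=0.05):
        z = -special.ndtri(alpha / 2.0)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    def fe_table(self, alpha=0.05) -> pd.DataFrame:
        """Fixed effects on the exponentiated scale (OR or exp(b)) with CIs."""
        ci = self.conf_int(alpha)[: self.model.k_fe]
        return pd.DataFrame({
            "predictor": self.model.exog_names,
            "estimate": np.exp(self.fe_params),
            "ci_low": np.exp(ci[:, 0]),
            "ci_high": np.exp(ci[:, 1]),
            "scale": self.scale_label,
        })

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} (adaptive Gauss-Hermite, {self.nagq or 'no'} points)",
            f"groups: {self.model.n_groups}  obs: {self.model.nobs}  "
            f"llf: {self.llf:.4f}  AIC: {self.aic:.4f}  converged: {self.converged}",
            f"random-intercept sd: {self.re_sd:.4f}",
            f"{'parameter':<24}{'est':>10}{'se':>10}{'[0.025':>10}{'0.975]':>10}",
        ]
        ci = self.conf_int()
        for name, est, se, (lo, hi) in zip(self.param_names, self.params, self.bse, ci):
            lines.append(f"{name:<24}{est:>10.4f}{se:>10.4f}{lo:>10.4f}{hi:>10.4f}")
        return "\n".join(lines)
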