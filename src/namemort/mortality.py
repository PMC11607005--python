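"""Maximum-likelihood Gompertz mortality estimation from doubly-truncated deaths.

Each record contributes the log of the Gompertz proportional-hazard death-age
density *conditioned on the death being observable*, i.e. falling inside the
record's birth-cohort-specific age window [L_i, U_i] implied by the calendar
observation window:

    ll_i = w_i * [ log h(x_i) + log S(x_i) - log(S(L_i) - S(U_i)) ]

The model is maximized over (log a0, b0, beta) with an analytic gradient; the
covariance comes from the inverse observed information (numerical Hessian of
the analytic gradient).  Hazard ratios are exp(beta) with Wald intervals;
e65-type functionals get parametric-bootstrap intervals over the joint
coefficient covariance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .gompertz import (
    GompertzParams,
    calibrate_from_e65,
    remaining_life_expectancy,
)
from .synthetic import TruncationWindow, is_foreign_born, observation_windows

__all__ = [
    "GompertzProportionalHazards",
    "truncated_loglik",
    "prepare_observations",
    "nativity_effect",
    "fit_group_nativity_tables",
    "descriptive_stats",
    "fe_linear_check",
    "calibrate_from_e65",
]

_B_SERIES = 1e-6  # below this |b0| use series forms of g and dg/db


def _g(b, t):
    t = np.asarray(t, dtype=float)
    if abs(b) < 1e-12:
        return t.copy()
    return np.expm1(b * t) / b


def _dg_db(b, t):
    """d/db of (e^{bt}-1)/b, with a series form near b = 0."""
    t = np.asarray(t, dtype=float)
    if abs(b) < _B_SERIES:
        return t**2 / 2.0 + b * t**3 / 3.0 + b**2 * t**4 / 8.0
    return (t * np.exp(b * t) * b - np.expm1(b * t)) / b**2


def _log1mexp(delta):
    """log(1 - e^{-delta}) for delta > 0, stable over the whole range."""
    delta = np.asarray(delta, dtype=float)
    out = np.empty_like(delta)
    small = delta < np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out[small] = np.log(-np.expm1(-delta[small]))
        out[~small] = np.log1p(-np.exp(-delta[~small]))
    return out


def _unpack(theta, p):
    return theta[0], theta[1], np.asarray(theta[2:]) if p else np.zeros(0)


def _loglik_grad(theta, t_x, z, t_lo, t_up, w):
    """Weighted truncated log-likelihood and its gradient in (u, b, beta).

    ``t_*`` are ages measured from the origin; ``t_up`` may be +inf.
    """
    p = z.shape[1]
    u, b, beta = _unpack(theta, p)
    lp = z @ beta if p else np.zeros_like(t_x)
    scale = np.exp(u + lp)

    g_x = _g(b, t_x)
    g_lo = _g(b, t_lo)
    h_x = scale * g_x
    h_lo = scale * g_lo

    finite_up = np.isfinite(t_up)
    t_up_f = np.where(finite_up, t_up, 0.0)
    h_up = np.where(finite_up, scale * _g(b, t_up_f), np.inf)
    delta = h_up - h_lo
    if np.any(delta <= 1e-14):
        bad = int(np.argmax(delta <= 1e-14))
        raise ValueError(
            f"observation {bad}: survival over its window [L, U] is degenerate "
            "(S(L) = S(U) to machine precision)"
        )

    logf = u + lp + b * t_x - h_x
    log_d = -h_lo + _log1mexp(delta)
    ll = float(np.sum(w * (logf - log_d)))

    # gradient pieces; for the denominator use
    # d(logD) = (-dH_L + r dH_U) / (1 - r), r = e^{-delta}
    r = np.where(finite_up, np.exp(-np.minimum(delta, 700.0)), 0.0)
    one_m_r = -np.expm1(-np.minimum(delta, 700.0))
    one_m_r = np.where(finite_up, one_m_r, 1.0)

    dh_x_db = scale * _dg_db(b, t_x)
    dh_lo_db = scale * _dg_db(b, t_lo)
    dh_up_db = np.where(finite_up, scale * _dg_db(b, t_up_f), 0.0)
    h_up_r = np.where(finite_up, scale * _g(b, t_up_f) * r, 0.0)

    # common per-record scores
    s_u = (1.0 - h_x) + (h_lo - h_up_r) / one_m_r
    s_b = (t_x - dh_x_db) + (dh_lo_db - r * dh_up_db) / one_m_r

    grad = np.empty(2 + p)
    grad[0] = np.sum(w * s_u)
    grad[1] = np.sum(w * s_b)
    if p:
        grad[2:] = z.T @ (w * s_u)
    return ll, grad


def truncated_loglik(
    params: GompertzParams, x, covariates=None, lower=None, upper=None, weight=None
) -> float:
    """Log-likelihood of death ages conditioned on observability in [L, U].

    ``lower`` defaults to the age origin (left bound = no extra truncation)
    and ``upper`` to +inf, in which case the value reduces to the plain
    (untruncated) Gompertz log density summed over records.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    n = x.size
    z = (
        np.atleast_2d(np.asarray(covariates, dtype=float)).reshape(n, -1)
        if covariates is not None
        else np.zeros((n, 0))
    )
    lo = np.full(n, params.age_origin) if lower is None else np.atleast_1d(np.asarray(lower, float))
    up = np.full(n, np.inf) if upper is None else np.atleast_1d(np.asarray(upper, float))
    w = np.ones(n) if weight is None else np.atleast_1d(np.asarray(weight, float))
    theta = np.concatenate([[np.log(params.a0), params.b0], params.beta[: z.shape[1]]])
    if z.shape[1] != params.beta.size:
        raise ValueError("covariate dimension does not match params.beta")
    ll, _ = _loglik_grad(
        theta, x - params.age_origin, z, lo - params.age_origin, up - params.age_origin, w
    )
    return ll


class GompertzProportionalHazards(BaseEstimator):
    """Truncated Gompertz proportional-hazard mortality model.

    Parameters
    ----------
    age_origin : float
        Age from which exposure is measured (default 65; the model describes
        over-65 mortality).
    init : GompertzParams or None
        Optional starting values; by default a moment-matched start is used.
    max_iter, tol : optimizer controls (L-BFGS-B on (log a0, b0, beta)).
    n_restarts : extra seeded-jitter starts tried on non-convergence.
    random_state : seed for the restart jitter.

    Attributes (after ``fit``)
    --------------------------
    a0_, b0_, coef_ : point estimates; ``params_`` bundles them.
    covariance_ : (2+p)x(2+p) inverse observed information in
        (log a0, b0, beta) order, or None if the Hessian was singular.
    loglik_, converged_, n_iter_, grad_norm_ : fit diagnostics.
    """

    def __init__(
        self,
        age_origin: float = 65.0,
        init: GompertzParams | None = None,
        max_iter: int = 500,
        tol: float = 1e-10,
        n_restarts: int = 3,
        random_state: int = 0,
    ):
        self.age_origin = age_origin
        self.init = init
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y, *, lower=None, upper=None, sample_weight=None):
        """Fit to death ages ``y`` with covariates ``X`` and windows [L, U].

        ``X`` may be None for a baseline-only fit.  ``lower``/``upper`` are
        per-record observable-age bounds; ``upper`` may be +inf.
        """
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if n == 0:
            raise ValueError("no observations")
        if X is None:
            z = np.zeros((n, 0))
            self.feature_names_in_ = np.array([], dtype=object)
        else:
            if isinstance(X, pd.DataFrame):
                self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            else:
                self.feature_names_in_ = None
            z = np.asarray(X, dtype=float).reshape(n, -1)
            if not np.all(np.isfinite(z)):
                raise ValueError("covariates contain non-finite values")
        p = z.shape[1]
        lo = (
            np.full(n, self.age_origin)
            if lower is None
            else np.asarray(lower, dtype=float).ravel()
        )
        up = np.full(n, np.inf) if upper is None else np.asarray(upper, dtype=float).ravel()
        w = (
            np.ones(n)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float).ravel()
        )
        if np.any(w < 0):
            raise ValueError("sample_weight must be nonnegative")
        bad = (y < lo - 1e-9) | (y > up + 1e-9)
        if np.any(bad):
            raise ValueError(
                f"{int(bad.sum())} observation(s) fall outside their [L, U] window "
                f"(first offending index {int(np.flatnonzero(bad)[0])}); "
                "records appear mis-filtered for the truncation design"
            )
        if np.any(lo < self.age_origin - 1e-9):
            raise ValueError("lower window bound below age_origin")

        t_x, t_lo, t_up = y - self.age_origin, lo - self.age_origin, up - self.age_origin
        theta0 = self._initial_theta(t_x, w, p)

        def negll(theta):
            ll, grad = _loglik_grad(theta, t_x, z, t_lo, t_up, w)
            if not np.isfinite(ll):
                return np.inf, np.zeros_like(theta)
            return -ll, -grad

        rng = np.random.default_rng(self.random_state)
        best = None
        start = theta0
        for attempt in range(self.n_restarts + 1):
            res = optimize.minimize(
                negll,
                start,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
            gnorm = float(np.max(np.abs(res.jac)))
            if res.success or gnorm < 1e-4 * max(1.0, np.sum(w)):
                best = res if res.fun <= best.fun else best
                break
            start = theta0 + rng.normal(scale=0.2, size=theta0.size)
        else:
            raise RuntimeError(
                "truncated Gompertz fit did not converge after "
                f"{self.n_restarts + 1} starts: status={best.message!r}, "
                f"best loglik={-best.fun:.6g}, grad norm={np.max(np.abs(best.jac)):.3g}"
            )

        theta = best.x
        self.a0_ = float(np.exp(theta[0]))
        self.b0_ = float(theta[1])
        self.coef_ = np.asarray(theta[2:]).copy()
        self.params_ = GompertzParams(self.a0_, self.b0_, self.coef_, self.age_origin)
        self.loglik_ = float(-best.fun)
        self.n_iter_ = int(best.nit)
        self.converged_ = bool(best.success or np.max(np.abs(best.jac)) < 1e-4 * max(1.0, np.sum(w)))
        self.grad_norm_ = float(np.max(np.abs(best.jac)))
        self.n_obs_ = n

        self.covariance_ = self._observed_info_cov(theta, t_x, z, t_lo, t_up, w)
        self.se_ = (
            np.sqrt(np.diag(self.covariance_)) if self.covariance_ is not None else None
        )
        return self

    def _initial_theta(self, t_x, w, p):
        if self.init is not None:
            beta0 = np.zeros(p)
            beta0[: min(p, self.init.beta.size)] = self.init.beta[:p]
            return np.concatenate([[np.log(self.init.a0), self.init.b0], beta0])
        mean_rem = max(float(np.average(t_x, weights=w)), 0.5)
        b0 = 0.09

        def f(log_a):
            pp = GompertzParams(np.exp(log_a), b0, age_origin=self.age_origin)
            return remaining_life_expectancy(pp, method="closed_form") - mean_rem

        try:
            u0 = optimize.brentq(f, -14.0, 2.0)
        except ValueError:
            u0 = np.log(1.0 / mean_rem)
        return np.concatenate([[u0, b0], np.zeros(p)])

    def _observed_info_cov(self, theta, t_x, z, t_lo, t_up, w):
        k = theta.size
        hess = np.empty((k, k))
        step = 1e-5 * np.maximum(1.0, np.abs(theta))
        for j in range(k):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += step[j]
            tm[j] -= step[j]
            _, gp = _loglik_grad(tp, t_x, z, t_lo, t_up, w)
            _, gm = _loglik_grad(tm, t_x, z, t_lo, t_up, w)
            hess[:, j] = (gp - gm) / (2 * step[j])
        hess = (hess + hess.T) / 2.0
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            return None
        if np.any(np.diag(cov) <= 0):
            return None
        return cov

    # -- inference ---------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")

    def parameter_names(self):
        self._check_fitted()
        if self.feature_names_in_ is not None and len(self.feature_names_in_):
            beta_names = [str(c) for c in self.feature_names_in_]
        else:
            beta_names = [f"beta{j}" for j in range(self.coef_.size)]
        return ["log_a0", "b0"] + beta_names

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald intervals on (log a0, b0, beta)."""
        from scipy.stats import norm

        self._check_fitted()
        if self.covariance_ is None:
            raise RuntimeError("covariance unavailable (singular observed information)")
        est = np.concatenate([[np.log(self.a0_), self.b0_], self.coef_])
        zc = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "estimate": est,
                "lower": est - zc * self.se_,
                "upper": est + zc * self.se_,
            },
            index=self.parameter_names(),
        )

    def hazard_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """exp(beta) with exponentiated Wald intervals."""
        ci = self.conf_int(alpha).iloc[2:]
        return np.exp(ci).rename(
            columns={"estimate": "hazard_ratio", "lower": "lower", "upper": "upper"}
        )

    def e65(self, profile=None, method: str = "quadrature") -> float:
        """Expected death age conditional on reaching the age origin, for a
        covariate profile (defaults to the baseline, all-zero profile)."""
        self._check_fitted()
        lp = 0.0
        if profile is not None and self.coef_.size:
            lp = float(np.asarray(profile, dtype=float) @ self.coef_)
        return self.age_origin + remaining_life_expectancy(self.params_, lp, method=method)

    def predict(self, X) -> np.ndarray:
        """Per-record expected age at death given covariates (e65 profile-wise)."""
        self._check_fitted()
        z = np.asarray(X, dtype=float).reshape(len(X), -1)
        return np.array([self.e65(row, method="closed_form") for row in z])

    def _sample_params(self, n_draws: int, seed) -> np.ndarray:
        if self.covariance_ is None:
            raise RuntimeError("covariance unavailable (singular observed information)")
        rng = np.random.default_rng(seed)
        mean = np.concatenate([[np.log(self.a0_), self.b0_], self.coef_])
        return rng.multivariate_normal(mean, self.covariance_, size=n_draws)

    def e65_interval(
        self, profile=None, alpha: float = 0.05, n_boot: int = 1000, seed=0
    ) -> tuple[float, float, float]:
        """(estimate, lower, upper) for e65 at a profile.

        The interval is a parametric bootstrap over the coefficient
        covariance: draw (log a0, b0, beta) from the asymptotic normal,
        recompute e65 per draw (closed form), take percentiles.
        """
        self._check_fitted()
        est = self.e65(profile)
        draws = self._sample_params(n_boot, seed)
        vals = self._e65_of_draws(draws, profile)
        lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return est, float(lo), float(hi)

    def _e65_of_draws(self, draws, profile) -> np.ndarray:
        z = (
            np.zeros(self.coef_.size)
            if profile is None
            else np.asarray(profile, dtype=float)
        )
        out = np.empty(len(draws))
        for i, th in enumerate(draws):
            pp = GompertzParams(np.exp(th[0]), th[1], th[2:], self.age_origin)
            lp = float(z @ th[2:]) if z.size else 0.0
            out[i] = self.age_origin + remaining_life_expectancy(
                pp, lp, method="closed_form"
            )
        return out


def prepare_observations(
    records: pd.DataFrame,
    window: TruncationWindow | None = None,
    age_origin: float = 65.0,
    covariate_columns=None,
):
    """Turn truncated person records into fitting arrays (x, Z, L, U, w).

    Recorded integer death ages are treated as mid-year events (x + 0.5);
    per-record windows come from ``observation_windows``.  By default the
    single covariate is the foreign-born indicator derived from the
    birthplace code.
    """
    window = window or TruncationWindow()
    x = records["death_age"].to_numpy(dtype=float) + 0.5
    lower, upper = observation_windows(records["birth_year"], window, age_origin)
    if covariate_columns is None:
        z = pd.DataFrame(
            {"foreign_born": is_foreign_born(records["birthplace_code"]).astype(float)},
            index=records.index,
        )
    else:
        z = records.loc[:, list(covariate_columns)].astype(float)
    w = (
        records["weight"].to_numpy(dtype=float)
        if "weight" in records.columns
        else np.ones(len(records))
    )
    return x, z, lower, upper, w


def nativity_effect(
    fit: GompertzProportionalHazards,
    feature: int | str = 0,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed=0,
) -> dict:
    """Foreign-born effect: hazard ratio and the implied e65 difference.

    Returns a dict with the hazard ratio exp(beta_fb) and Wald CI, e65 for
    the US-born (Z=0) and foreign-born (Z=1) profiles, and
    delta_e65 = e65(foreign-born) - e65(US-born) with a seeded parametric
    bootstrap CI propagated over the joint coefficient covariance.
    """
    fit._check_fitted()
    if fit.coef_.size == 0:
        raise ValueError("fit has no covariates; a foreign-born indicator is required")
    if isinstance(feature, str):
        names = fit.parameter_names()[2:]
        if feature not in names:
            raise ValueError(f"no coefficient named {feature!r}; have {names}")
        feature = names.index(feature)
    k = fit.coef_.size
    prof_us = np.zeros(k)
    prof_fb = np.zeros(k)
    prof_fb[feature] = 1.0

    beta = fit.coef_[feature]
    hr = float(np.exp(beta))
    if fit.covariance_ is not None:
        se = fit.se_[2 + feature]
        from scipy.stats import norm

        zc = norm.ppf(1 - alpha / 2)
        hr_ci = (float(np.exp(beta - zc * se)), float(np.exp(beta + zc * se)))
    else:
        hr_ci = (np.nan, np.nan)

    e_us = fit.e65(prof_us)
    e_fb = fit.e65(prof_fb)
    delta = e_fb - e_us
    if beta == 0.0:
        delta = 0.0
    if fit.covariance_ is not None:
        draws = fit._sample_params(n_boot, seed)
        v_us = fit._e65_of_draws(draws, prof_us)
        v_fb = fit._e65_of_draws(draws, prof_fb)
        q = [100 * alpha / 2, 100 * (1 - alpha / 2)]
        d_lo, d_hi = np.percentile(v_fb - v_us, q)
        us_lo, us_hi = np.percentile(v_us, q)
        fb_lo, fb_hi = np.percentile(v_fb, q)
    else:
        d_lo = d_hi = us_lo = us_hi = fb_lo = fb_hi = np.nan
    return {
        "hazard_ratio": hr,
        "hr_lower": hr_ci[0],
        "hr_upper": hr_ci[1],
        "e65_us": e_us,
        "e65_us_lower": float(us_lo),
        "e65_us_upper": float(us_hi),
        "e65_fb": e_fb,
        "e65_fb_lower": float(fb_lo),
        "e65_fb_upper": float(fb_hi),
        "delta_e65": float(delta),
        "delta_e65_lower": float(d_lo),
        "delta_e65_upper": float(d_hi),
    }


def fit_group_nativity_tables(
    records: pd.DataFrame,
    window: TruncationWindow | None = None,
    group_column: str = "group",
    min_cell: int = 50,
    n_boot: int = 1000,
    seed=0,
    age_origin: float = 65.0,
):
    """Per-(group, sex) truncated fits with a foreign-born indicator.

    Returns (hazard-ratio/effect table, e65-by-nativity table, fits dict).
    Cells with fewer than ``min_cell`` records on either nativity side are
    skipped (reported with NaN rows).
    """
    window = window or TruncationWindow()
    rows2, rows3, fits = [], [], {}
    ss = np.random.SeedSequence(seed)
    for (group, sex), cell in records.groupby([group_column, "sex"], sort=True):
        fb = is_foreign_born(cell["birthplace_code"])
        cell_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        if fb.sum() < min_cell or (~fb).sum() < min_cell:
            eff = {k: np.nan for k in (
                "hazard_ratio", "hr_lower", "hr_upper", "e65_us", "e65_us_lower",
                "e65_us_upper", "e65_fb", "e65_fb_lower", "e65_fb_upper",
                "delta_e65", "delta_e65_lower", "delta_e65_upper")}
        else:
            x, z, lo, up, w = prepare_observations(cell, window, age_origin)
            model = GompertzProportionalHazards(age_origin=age_origin)
            model.fit(z, x, lower=lo, upper=up, sample_weight=w)
            fits[(group, sex)] = model
            eff = nativity_effect(model, "foreign_born", n_boot=n_boot, seed=cell_seed)
        rows2.append(
            {
                "group": group,
                "sex": sex,
                "hazard_ratio": eff["hazard_ratio"],
                "hr_lower": eff["hr_lower"],
                "hr_upper": eff["hr_upper"],
                "effect_e65": eff["delta_e65"],
                "effect_e65_lower": eff["delta_e65_lower"],
                "effect_e65_upper": eff["delta_e65_upper"],
            }
        )
        rows3.append(
            {
                "group": group,
                "sex": sex,
                "e65_us": eff["e65_us"],
                "e65_us_lower": eff["e65_us_lower"],
                "e65_us_upper": eff["e65_us_upper"],
                "e65_fb": eff["e65_fb"],
                "e65_fb_lower": eff["e65_fb_lower"],
                "e65_fb_upper": eff["e65_fb_upper"],
            }
        )
    return pd.DataFrame(rows2), pd.DataFrame(rows3), fits


def descriptive_stats(
    records: pd.DataFrame, by=("group", "sex", "nativity")
) -> pd.DataFrame:
    """n, mean and modal death age, mean birth year per grouping cell.

    Means are weight-weighted when a weight column is present; the modal age
    is the most frequent recorded integer age (smallest age on ties).
    """
    df = records.copy()
    if "nativity" in by and "nativity" not in df.columns:
        df["nativity"] = np.where(
            is_foreign_born(df["birthplace_code"]), "foreign_born", "us_born"
        )
    w = df["weight"] if "weight" in df.columns else pd.Series(1.0, index=df.index)
    df["_w"] = w

    rows = []
    for key, cell in df.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        cw = cell["_w"]
        counts = cell.groupby("death_age")["_w"].sum()
        mode = int(counts[counts == counts.max()].index.min())
        rows.append(
            dict(zip(by, key))
            | {
                "n": int(len(cell)),
                "mean_death_age": float(np.average(cell["death_age"], weights=cw)),
                "modal_death_age": mode,
                "mean_birth_year": float(np.average(cell["birth_year"], weights=cw)),
            }
        )
    return pd.DataFrame(rows)


def fe_linear_check(
    records: pd.DataFrame,
    window: TruncationWindow | None = None,
    covariate_columns=("foreign_born",),
) -> pd.DataFrame:
    """OLS of death age on covariates with birth-year fixed effects.

    A robustness companion to the truncated MLE: the cohort fixed effects
    absorb variation in which part of each cohort's death distribution is
    observable, mitigating (not removing) truncation bias.  Returns the
    covariate coefficient table; birth-year dummies are absorbed and not
    reported.
    """
    import statsmodels.api as sm

    df = records.copy()
    if window is not None:
        from .synthetic import apply_truncation

        df = apply_truncation(df, window)
    if df["birth_year"].nunique() < 1 or len(df) == 0:
        raise ValueError("no records to regress")
    if "foreign_born" in covariate_columns and "foreign_born" not in df.columns:
        df["foreign_born"] = is_foreign_born(df["birthplace_code"]).astype(float)

    x = df.loc[:, list(covariate_columns)].astype(float)
    const_cols = [c for c in x.columns if x[c].nunique() <= 1]
    if const_cols:
        raise ValueError(f"collinear (constant) covariate columns: {const_cols}")
    dummies = pd.get_dummies(df["birth_year"].astype(int), prefix="by", drop_first=True)
    design = pd.concat([x, dummies.astype(float)], axis=1)
    design = sm.add_constant(design)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = x.corr().abs()
        dup = [
            (a, b)
            for i, a in enumerate(x.columns)
            for b in x.columns[i + 1 :]
            if corr.loc[a, b] > 1 - 1e-10
        ]
        raise ValueError(f"design matrix is rank deficient; collinear covariates: {dup or list(x.columns)}")
    w = df["weight"] if "weight" in df.columns else None
    model = sm.WLS(df["death_age"].astype(float), design, weights=w if w is not None else 1.0)
    res = model.fit()
    ci = res.conf_int()
    table = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
            "lower": ci[0],
            "upper": ci[1],
        }
    )
    return table.loc[["const"] + list(covariate_columns)]
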