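"""Gompertz proportional-hazard distribution utilities.

The adult-mortality hazard is modelled as

    h(x | Z) = a0 * exp(b0 * (x - age_origin)) * exp(beta . Z)

i.e. a Gompertz baseline (level ``a0`` at the age origin, log-slope ``b0``)
scaled multiplicatively by covariates through a log-linear predictor.  All
survival quantities here are conditional on being alive at ``age_origin``
(default 65), which is how the over-65 analysis parameterizes mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special

__all__ = [
    "GompertzParams",
    "calibrate_from_e65",
    "cumulative_hazard",
    "survival",
    "log_survival",
    "hazard",
    "log_density",
    "sample_death_age",
    "remaining_life_expectancy",
    "e65",
]

# below this |b0| the exact expm1 form is replaced by its limit to avoid 0/0
_B_TINY = 1e-12


@dataclass
class GompertzParams:
    """Parameters of the proportional-hazard Gompertz model.

    Attributes
    ----------
    a0 : float
        Baseline hazard level at ``age_origin`` (per year, > 0).
    b0 : float
        Log-rate of hazard increase with age (per year).
    beta : ndarray
        Covariate log-hazard coefficients; ``exp(beta)`` are hazard ratios.
    age_origin : float
        Age from which exposure is measured (years).
    """

    a0: float
    b0: float
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    age_origin: float = 65.0

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not np.isfinite(self.a0) or self.a0 <= 0:
            raise ValueError(f"a0 must be positive and finite, got {self.a0}")
        if not np.isfinite(self.b0):
            raise ValueError(f"b0 must be finite, got {self.b0}")

    def linear_predictor(self, covariates) -> np.ndarray:
        """beta . Z for a covariate vector or matrix (rows = records)."""
        z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if z.shape[1] != self.beta.size:
            raise ValueError(
                f"covariate dimension {z.shape[1]} != beta dimension {self.beta.size}"
            )
        return z @ self.beta


def _gfun(b: float, t: np.ndarray) -> np.ndarray:
    """(exp(b*t) - 1) / b, continuous at b = 0 where it equals t."""
    t = np.asarray(t, dtype=float)
    if abs(b) < _B_TINY:
        return t.copy() if t.shape else np.array(t, dtype=float)
    return np.expm1(b * t) / b


def cumulative_hazard(params: GompertzParams, x, lin_pred=0.0) -> np.ndarray:
    """Integrated hazard from ``age_origin`` to age ``x``.

    H(x) = (a0 * e^{beta.Z} / b0) * (e^{b0 (x - origin)} - 1)
    """
    t = np.asarray(x, dtype=float) - params.age_origin
    if np.any(t < -1e-9):
        raise ValueError("age below age_origin: no exposure is defined there")
    t = np.maximum(t, 0.0)
    return params.a0 * np.exp(lin_pred) * _gfun(params.b0, t)


def log_survival(params: GompertzParams, x, lin_pred=0.0) -> np.ndarray:
    return -cumulative_hazard(params, x, lin_pred)


def survival(params: GompertzParams, x, lin_pred=0.0) -> np.ndarray:
    """P(T > x | T > age_origin)."""
    return np.exp(log_survival(params, x, lin_pred))


def hazard(params: GompertzParams, x, lin_pred=0.0) -> np.ndarray:
    t = np.asarray(x, dtype=float) - params.age_origin
    if np.any(t < -1e-9):
        raise ValueError("age below age_origin: hazard undefined")
    return params.a0 * np.exp(params.b0 * np.maximum(t, 0.0) + lin_pred)


def log_density(params: GompertzParams, x, lin_pred=0.0) -> np.ndarray:
    """log f(x) = log h(x) + log S(x), the (untruncated) death-age density."""
    t = np.asarray(x, dtype=float) - params.age_origin
    lh = np.log(params.a0) + params.b0 * t + lin_pred
    return lh - cumulative_hazard(params, x, lin_pred)


def sample_death_age(params: GompertzParams, lin_pred=0.0, size=None, rng=None):
    """Draw death ages by inverse-CDF sampling.

    Solves S(t) = U for U ~ Uniform(0, 1):
    t = log1p(-log(U) * b0 / (a0 e^{lp})) / b0, with the exponential limit at
    b0 = 0.  For b0 < 0 the distribution is improper (the cumulative hazard
    plateaus); draws landing beyond the plateau come back as ``inf``.
    """
    rng = np.random.default_rng(rng)
    lp = np.asarray(lin_pred, dtype=float)
    if size is None:
        size = lp.shape if lp.shape else None
    u = rng.random(size)
    rate = params.a0 * np.exp(lp)
    e = -np.log(u)  # standard exponential
    if abs(params.b0) < _B_TINY:
        t = e / rate
    else:
        arg = 1.0 + params.b0 * e / rate
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / params.b0, np.inf)
    return params.age_origin + t


def remaining_life_expectancy(
    params: GompertzParams, lin_pred: float = 0.0, method: str = "quadrature"
) -> float:
    """E[T - age_origin | T > age_origin] = integral of S over (0, inf).

    ``method='quadrature'`` uses adaptive quadrature (tolerance 1e-10);
    ``method='closed_form'`` uses the exponential-integral identity
    integral = e^A E1(A) / b0 with A = a0 e^{lp} / b0, which the quadrature
    route is cross-checked against in the test suite.
    """
    a = params.a0 * np.exp(lin_pred)
    b = params.b0
    if b < -_B_TINY:
        raise ValueError(
            "b0 < 0: survival plateaus above zero and the life-expectancy "
            "integral diverges (improper distribution)"
        )
    if abs(b) < _B_TINY:
        return 1.0 / a
    big_a = a / b
    if method == "closed_form":
        if big_a > 700:  # e^A overflows; use the asymptotic e^A E1(A) ~ 1/A
            return float((1.0 / big_a) / b)
        return float(np.exp(big_a) * special.exp1(big_a) / b)
    if method != "quadrature":
        raise ValueError(f"unknown method {method!r}")
    with np.errstate(over="ignore"):
        val, _ = integrate.quad(
            lambda t: np.exp(-big_a * min(np.expm1(b * t), 1e300)),
            0.0,
            np.inf,
            epsabs=1e-10,
            epsrel=1e-10,
            limit=200,
        )
    return float(val)


def e65(params: GompertzParams, lin_pred: float = 0.0, method: str = "quadrature") -> float:
    """Expected age at death conditional on surviving to the age origin."""
    return params.age_origin + remaining_life_expectancy(params, lin_pred, method=method)


def calibrate_from_e65(
    e65_base: float,
    e65_alt: float,
    hazard_ratio: float,
    age_origin: float = 65.0,
    b_bracket: tuple[float, float] = (1e-4, 1.0),
) -> GompertzParams:
    """Solve for (a0, b0) so the model reproduces two conditional life expectancies.

    Finds the unique (a0, b0) such that the baseline profile has conditional
    life expectancy ``e65_base`` and a profile whose hazard is scaled by
    ``hazard_ratio`` has ``e65_alt``.  Two equations, two unknowns: for a
    given slope b0, a0 is pinned by the baseline e65 (monotone, solved by
    bisection); the hazard-ratio profile's e65 then selects b0.  The returned
    parameters carry ``beta = [log(hazard_ratio)]`` so the scaled profile is
    covariate value Z = 1.
    """
    from scipy import optimize

    target_base = e65_base - age_origin
    if target_base <= 0:
        raise ValueError("e65_base must exceed age_origin")
    log_hr = float(np.log(hazard_ratio))
    if abs(log_hr) < 1e-10:
        raise ValueError(
            "hazard_ratio of 1 leaves b0 unidentified; specify b0 directly"
        )

    def a_for(b: float) -> float:
        def f(log_a: float) -> float:
            p = GompertzParams(np.exp(log_a), b, age_origin=age_origin)
            return remaining_life_expectancy(p, method="closed_form") - target_base

        return float(np.exp(optimize.brentq(f, -30.0, 5.0, xtol=1e-13)))

    def gap_error(b: float) -> float:
        a = a_for(b)
        p = GompertzParams(a, b, beta=[log_hr], age_origin=age_origin)
        alt = age_origin + remaining_life_expectancy(p, lin_pred=log_hr, method="closed_form")
        return alt - e65_alt

    lo, hi = b_bracket
    flo, fhi = gap_error(lo), gap_error(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"no slope b0 in {b_bracket} reproduces the requested e65 pair "
            f"(gap errors {flo:.3f} and {fhi:.3f})"
        )
    b0 = float(optimize.brentq(gap_error, lo, hi, xtol=1e-12))
    a0 = a_for(b0)
    return GompertzParams(a0, b0, beta=[log_hr], age_origin=age_origin)
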