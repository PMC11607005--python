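"""Calibrated-simulation experiments: effect recovery, CI coverage, oracles.

These routines wire the synthetic generator to the estimators under the
study's reference conditions and measure what comes back: simulate a
two-nativity cohort at the calibrated hazard regime, fit the truncated MLE,
and report the recovered hazard ratio and e65 quantities; run replicate fits
to measure Wald-interval coverage; compare the stabilized likelihood against
quadrature-normalized brute force; and train the name classifier on separable
and on signal-free corpora.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

from .classifier import bigram_logistic_baseline, train_name_classifier
from .gompertz import GompertzParams, calibrate_from_e65
from .mortality import GompertzProportionalHazards, nativity_effect, truncated_loglik
from .names import make_group_spec, generate_name_pairs
from .synthetic import REFERENCE_CONDITIONS, simulate_nativity_observations

__all__ = [
    "calibrated_params",
    "hr_recovery_experiment",
    "coverage_experiment",
    "loglik_oracle_experiment",
    "separable_classifier_experiment",
    "no_signal_classifier_experiment",
]


def calibrated_params(group: str, sex: str) -> GompertzParams:
    """Gompertz parameters calibrated to one (group, sex) reference cell."""
    cond = REFERENCE_CONDITIONS[(group, sex)]
    return calibrate_from_e65(cond["e65_us"], cond["e65_fb"], cond["hazard_ratio"])


def hr_recovery_experiment(
    group: str,
    sex: str,
    n_per_group: int = 20_000,
    seed: int = 0,
    n_boot: int = 1000,
) -> dict:
    """Simulate the truncated two-nativity design and refit it.

    Returns the generating values alongside the recovered hazard ratio,
    foreign-born/US-born e65 and their gap, plus standard errors for
    tolerance checks.
    """
    params = calibrated_params(group, sex)
    x, z, lo, up, w = simulate_nativity_observations(params, n_per_group, seed=seed)
    fit = GompertzProportionalHazards().fit(z, x, lower=lo, upper=up, sample_weight=w)
    eff = nativity_effect(fit, 0, n_boot=n_boot, seed=seed + 1)
    cond = REFERENCE_CONDITIONS[(group, sex)]
    draws = fit._sample_params(n_boot, seed + 2)
    d_us = fit._e65_of_draws(draws, np.zeros(1))
    d_fb = fit._e65_of_draws(draws, np.ones(1))
    return {
        "group": group,
        "sex": sex,
        "n_retained": int(x.size),
        "beta_true": float(params.beta[0]),
        "beta_hat": float(fit.coef_[0]),
        "se_beta": float(fit.se_[2]),
        "hazard_ratio": eff["hazard_ratio"],
        "hr_true": cond["hazard_ratio"],
        "e65_us": eff["e65_us"],
        "e65_fb": eff["e65_fb"],
        "e65_us_true": cond["e65_us"],
        "e65_fb_true": cond["e65_fb"],
        "delta_e65": eff["delta_e65"],
        "delta_e65_true": cond["e65_fb"] - cond["e65_us"],
        "se_e65_fb": float(d_fb.std()),
        "se_delta_e65": float((d_fb - d_us).std()),
    }


def coverage_experiment(
    params: GompertzParams | None = None,
    n_reps: int = 200,
    n_per_group: int = 10_000,
    seed: int = 0,
) -> dict:
    """Empirical coverage of the 95% Wald CI for the foreign-born log hazard
    over replicate truncated simulations."""
    params = params or calibrated_params("mena", "male")
    beta_true = params.beta[0]
    hits = 0
    used = 0
    for rep in range(n_reps):
        x, z, lo, up, _ = simulate_nativity_observations(
            params, n_per_group, seed=seed + 7919 * rep
        )
        fit = GompertzProportionalHazards().fit(z, x, lower=lo, upper=up)
        if fit.se_ is None:
            continue
        half = 1.959963984540054 * fit.se_[2]
        hits += int(abs(fit.coef_[0] - beta_true) <= half)
        used += 1
    return {"coverage": hits / used, "n_reps": used, "n_per_group": n_per_group}


def _brute_truncated_loglik(params, x, lp, lower, upper):
    total = 0.0
    for xi, li, lo, up in zip(x, lp, lower, upper):
        def dens(t):
            h = params.a0 * np.exp(params.b0 * (t - params.age_origin) + li)
            ch = (
                params.a0
                * np.exp(li)
                * (np.expm1(params.b0 * (t - params.age_origin)) / params.b0)
            )
            return h * np.exp(-ch)

        norm, _ = integrate.quad(
            dens, lo, min(up, 250.0), epsabs=1e-13, epsrel=1e-13, limit=300
        )
        total += np.log(dens(xi)) - np.log(norm)
    return total


def loglik_oracle_experiment(n_instances: int = 100, seed: int = 0) -> dict:
    """Max |stabilized loglik - quadrature brute force| over random small
    doubly-truncated instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        p = GompertzParams(
            rng.uniform(0.005, 0.05), rng.uniform(0.05, 0.2), beta=[rng.normal(0, 0.5)]
        )
        n = int(rng.integers(1, 10))
        lo = 65.0 + rng.uniform(0, 10, n)
        up = lo + rng.uniform(1, 20, n)
        x = lo + (up - lo) * rng.uniform(0.05, 0.95, n)
        z = rng.integers(0, 2, n).astype(float).reshape(-1, 1)
        ll = truncated_loglik(p, x, covariates=z, lower=lo, upper=up)
        brute = _brute_truncated_loglik(p, x, z[:, 0] * p.beta[0], lo, up)
        worst = max(worst, abs(ll - brute))
    return {"max_abs_err": float(worst), "n_instances": n_instances}


def _labelled_corpus(spec_pos, spec_neg, n_per_class, seed):
    pos = [f"{g} {s}" for g, s in generate_name_pairs(spec_pos, n_per_class, seed)]
    neg = [f"{g} {s}" for g, s in generate_name_pairs(spec_neg, n_per_class, seed + 1)]
    labels = np.array([1] * n_per_class + [0] * n_per_class)
    return pos + neg, labels


def separable_classifier_experiment(
    n_per_class: int = 5000, seed: int = 0, n_epochs: int = 10
) -> dict:
    """Train on two well-separated character processes; report held-out
    metrics and the bag-of-bigrams logistic baseline on the same split."""
    from sklearn.model_selection import train_test_split

    spec_pos = make_group_spec(seed + 100, ["kh", "gh", "ab", "al", "ou"])
    spec_neg = make_group_spec(seed + 200, ["th", "er", "son", "an"])
    names, labels = _labelled_corpus(spec_pos, spec_neg, n_per_class, seed)
    clf, metrics = train_name_classifier(names, labels, seed=seed, n_epochs=n_epochs)
    x_tr, x_te, y_tr, y_te = train_test_split(
        names, labels, test_size=0.2, stratify=labels, random_state=seed
    )
    baseline = bigram_logistic_baseline(x_tr, y_tr, x_te, y_te)
    return {
        "f1": metrics.f1,
        "precision": metrics.precision,
        "recall": metrics.recall,
        "baseline_f1": baseline.f1,
        "n_test": metrics.n_test,
        "clf": clf,
        "names": names,
        "labels": labels,
    }


def no_signal_classifier_experiment(n_per_class: int = 2000, seed: int = 0) -> dict:
    """Identical generators for both classes: the classifier should land at
    chance-level F1."""
    spec = make_group_spec(seed + 300, ["kh", "th"])
    names, labels = _labelled_corpus(spec, spec, n_per_class, seed)
    _, metrics = train_name_classifier(names, labels, seed=seed)
    return {"f1": metrics.f1, "n_test": metrics.n_test}
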