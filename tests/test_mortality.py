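"""Truncated-likelihood, fitting, and table-level checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize

from namemort.gompertz import GompertzParams, e65, remaining_life_expectancy, sample_death_age
from namemort.mortality import (
    GompertzProportionalHazards,
    _loglik_grad,
    descriptive_stats,
    fe_linear_check,
    nativity_effect,
    truncated_loglik,
)
from namemort.synthetic import TruncationWindow, simulate_nativity_observations

from conftest import make_records


def brute_force_loglik(params, x, lp, lower, upper, weight):
    """Quadrature-normalized truncated log density, the independent oracle."""
    total = 0.0
    for xi, li, wi, lo, up in zip(x, lp, weight, lower, upper):
        def dens(t):
            h = params.a0 * np.exp(params.b0 * (t - params.age_origin) + li)
            ch = (
                params.a0
                * np.exp(li)
                * (np.expm1(params.b0 * (t - params.age_origin)) / params.b0)
            )
            return h * np.exp(-ch)

        norm, _ = integrate.quad(dens, lo, min(up, 200.0), epsabs=1e-13, epsrel=1e-13, limit=300)
        total += wi * (np.log(dens(xi)) - np.log(norm))
    return total


class TestTruncatedLoglik:
    def test_no_truncation_reduces_to_log_density(self):
        from namemort.gompertz import log_density

        p = GompertzParams(0.02, 0.09, beta=[-0.2])
        ll = truncated_loglik(p, [78.3], covariates=[[1.0]])
        assert ll == pytest.approx(float(log_density(p, 78.3, -0.2)), abs=1e-10)

    def test_matches_quadrature_oracle_small_set(self):
        rng = np.random.default_rng(5)
        p = GompertzParams(0.013, 0.11, beta=[-0.4])
        n = 5
        lo = 65.0 + rng.uniform(0, 8, n)
        up = lo + rng.uniform(2, 15, n)
        x = lo + (up - lo) * rng.uniform(0.1, 0.9, n)
        z = rng.integers(0, 2, n).astype(float).reshape(-1, 1)
        w = rng.uniform(0.5, 2.0, n)
        ll = truncated_loglik(p, x, covariates=z, lower=lo, upper=up, weight=w)
        brute = brute_force_loglik(p, x, z[:, 0] * p.beta[0], lo, up, w)
        assert ll == pytest.approx(brute, abs=1e-7)

    def test_random_instances_property(self):
        """Likelihood equals quadrature-normalized brute force on random
        small instances (doubly-truncated windows, mixed covariates)."""
        rng = np.random.default_rng(123)
        for _ in range(25):
            p = GompertzParams(
                rng.uniform(0.005, 0.05), rng.uniform(0.05, 0.2), beta=[rng.normal(0, 0.5)]
            )
            n = int(rng.integers(1, 10))
            lo = 65.0 + rng.uniform(0, 10, n)
            up = lo + rng.uniform(1, 20, n)
            x = lo + (up - lo) * rng.uniform(0.05, 0.95, n)
            z = rng.integers(0, 2, n).astype(float).reshape(-1, 1)
            w = np.ones(n)
            ll = truncated_loglik(p, x, covariates=z, lower=lo, upper=up, weight=w)
            brute = brute_force_loglik(p, x, z[:, 0] * p.beta[0], lo, up, w)
            assert ll == pytest.approx(brute, abs=1e-6)

    def test_weight_linearity(self):
        p = GompertzParams(0.02, 0.1)
        x = np.array([70.0, 75.0, 82.0])
        lo = np.full(3, 66.0)
        up = np.full(3, 90.0)
        base = truncated_loglik(p, x, lower=lo, upper=up)
        doubled = truncated_loglik(p, x, lower=lo, upper=up, weight=np.full(3, 2.0))
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_degenerate_window_error(self):
        p = GompertzParams(0.02, 0.1)
        with pytest.raises(ValueError, match="degenerate|machine precision"):
            truncated_loglik(p, [70.0], lower=[70.0], upper=[70.0])

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(9)
        n = 20
        lo = 65.0 + rng.uniform(0, 8, n)
        up = lo + rng.uniform(2, 15, n)
        # one side unbounded to exercise the U = inf branch
        up[:3] = np.inf
        x = np.where(np.isfinite(up), lo + (up - lo) * 0.5, lo + 5.0)
        z = rng.normal(size=(n, 2))
        w = rng.uniform(0.5, 2, n)
        theta = np.array([np.log(0.02), 0.1, -0.3, 0.2])
        args = (x - 65.0, z, lo - 65.0, up - 65.0, w)
        _, grad = _loglik_grad(theta, *args)
        num = optimize.approx_fprime(theta, lambda th: _loglik_grad(th, *args)[0], 1e-7)
        assert np.allclose(grad, num, rtol=1e-4, atol=1e-4)


class TestFit:
    def test_parameter_recovery_untruncated(self):
        rng = np.random.default_rng(21)
        n = 100_000
        p = GompertzParams(0.02, 0.09, beta=[np.log(0.8)])
        z = rng.integers(0, 2, n).astype(float).reshape(-1, 1)
        x = sample_death_age(p, lin_pred=z[:, 0] * p.beta[0], size=n, rng=rng)
        m = GompertzProportionalHazards().fit(z, x)
        est = np.array([np.log(m.a0_), m.b0_, m.coef_[0]])
        truth = np.array([np.log(0.02), 0.09, np.log(0.8)])
        assert np.all(np.abs(est - truth) < 3 * m.se_)

    def test_null_covariate_recovery(self, mena_men_params):
        """Two identical groups: beta within 3 SEs of 0, HR CI covers 1."""
        p0 = GompertzParams(mena_men_params.a0, mena_men_params.b0, beta=[0.0])
        x, z, lo, up, w = simulate_nativity_observations(p0, 8000, seed=17)
        m = GompertzProportionalHazards().fit(z, x, lower=lo, upper=up)
        assert abs(m.coef_[0]) < 3 * m.se_[2]
        hr = m.hazard_ratios()
        assert hr["lower"].iloc[0] < 1.0 < hr["upper"].iloc[0]

    def test_truncated_recovery_mena_men_design(self, mena_men_params):
        x, z, lo, up, w = simulate_nativity_observations(mena_men_params, 20_000, seed=1)
        m = GompertzProportionalHazards().fit(z, x, lower=lo, upper=up, sample_weight=w)
        beta_true = mena_men_params.beta[0]
        assert abs(m.coef_[0] - beta_true) < 3 * m.se_[2]
        assert np.exp(m.coef_[0]) == pytest.approx(0.64, abs=0.06)

    def test_weight_scaling_leaves_estimates_unchanged(self, mena_men_params):
        x, z, lo, up, w = simulate_nativity_observations(mena_men_params, 3000, seed=4)
        m1 = GompertzProportionalHazards().fit(z, x, lower=lo, upper=up, sample_weight=w)
        m2 = GompertzProportionalHazards().fit(z, x, lower=lo, upper=up, sample_weight=3.0 * w)
        assert m2.loglik_ == pytest.approx(3 * m1.loglik_, rel=1e-6)
        assert m2.a0_ == pytest.approx(m1.a0_, rel=1e-5)
        assert m2.coef_[0] == pytest.approx(m1.coef_[0], abs=1e-5)

    def test_misfiltered_record_rejected(self):
        m = GompertzProportionalHazards()
        with pytest.raises(ValueError, match="window"):
            m.fit(None, [72.0], lower=[73.0], upper=[90.0])

    def test_e65_origin_reparameterization_invariant(self, mena_men_params):
        """The same hazard expressed from origin 65 or origin 0 must give the
        same conditional life expectancy at 65."""
        p = mena_men_params
        a_from_zero = p.a0 * np.exp(-p.b0 * 65.0)
        p0 = GompertzParams(a_from_zero, p.b0, age_origin=0.0)
        # condition the origin-0 parameterization on surviving to 65
        eff_a65 = p0.a0 * np.exp(p0.b0 * 65.0)
        rem = remaining_life_expectancy(GompertzParams(eff_a65, p.b0, age_origin=65.0))
        assert 65.0 + rem == pytest.approx(e65(p), abs=1e-6)


class TestNativityEffect:
    def test_zero_beta_gives_unit_hr_and_zero_delta(self, mena_men_params):
        x, z, lo, up, w = simulate_nativity_observations(mena_men_params, 4000, seed=8)
        m = GompertzProportionalHazards().fit(z, x, lower=lo, upper=up)
        m.coef_[0] = 0.0  # force the null profile contrast
        m.params_ = GompertzParams(m.a0_, m.b0_, m.coef_, m.age_origin)
        eff = nativity_effect(m, 0, n_boot=50, seed=1)
        assert eff["hazard_ratio"] == 1.0
        assert eff["delta_e65"] == 0.0

    def test_sign_equivalence_hr_vs_delta_e65(self):
        """HR < 1 iff delta-e65 > 0 whenever b0 > 0, over a parameter grid."""
        for a0 in [0.005, 0.02, 0.05]:
            for b0 in [0.05, 0.1, 0.15]:
                for beta in [-0.5, -0.1, 0.1, 0.5]:
                    p = GompertzParams(a0, b0, beta=[beta])
                    delta = e65(p, lin_pred=beta, method="closed_form") - e65(
                        p, method="closed_form"
                    )
                    assert (np.exp(beta) < 1) == (delta > 0)

    def test_missing_indicator_error(self):
        m = GompertzProportionalHazards().fit(None, [75.0, 80.0, 71.0])
        with pytest.raises(ValueError, match="foreign-born|covariates"):
            nativity_effect(m)

    def test_interval_covers_estimate(self, mena_men_params):
        x, z, lo, up, w = simulate_nativity_observations(mena_men_params, 6000, seed=30)
        m = GompertzProportionalHazards().fit(z, x, lower=lo, upper=up)
        eff = nativity_effect(m, 0, n_boot=400, seed=2)
        assert eff["hr_lower"] <= eff["hazard_ratio"] <= eff["hr_upper"]
        assert eff["delta_e65_lower"] <= eff["delta_e65"] <= eff["delta_e65_upper"]


class TestDescriptives:
    def test_degenerate_single_age(self):
        df = make_records([{"death_age": 70, "death_year": 1990, "birth_year": 1920}] * 5)
        out = descriptive_stats(df, by=("group",))
        assert out.loc[0, "mean_death_age"] == 70
        assert out.loc[0, "modal_death_age"] == 70

    def test_mode_tie_breaks_to_smallest_age(self):
        rows = [{"death_age": 66} for _ in range(10)] + [{"death_age": 80} for _ in range(10)]
        out = descriptive_stats(make_records(rows), by=("group",))
        assert out.loc[0, "modal_death_age"] == 66

    def test_weighted_mean(self):
        rows = [
            {"death_age": 70, "weight": 3.0},
            {"death_age": 80, "weight": 1.0},
        ]
        out = descriptive_stats(make_records(rows), by=("group",))
        assert out.loc[0, "mean_death_age"] == pytest.approx(72.5)

    def test_nativity_split_derived_from_birthplace(self):
        rows = [
            {"birthplace_code": "LB", "death_age": 75},
            {"birthplace_code": "US-NY", "death_age": 70},
        ]
        out = descriptive_stats(make_records(rows), by=("nativity",))
        assert set(out["nativity"]) == {"foreign_born", "us_born"}


class TestFixedEffectsCheck:
    @staticmethod
    def _linear_records(seed=0, n=4000, effect=2.0, n_cohorts=20):
        rng = np.random.default_rng(seed)
        birth = rng.integers(1905, 1905 + n_cohorts, n)
        fb = rng.integers(0, 2, n)
        age = 70 + 0.1 * (birth - 1915) + effect * fb + rng.normal(0, 3, n)
        return make_records(
            [
                {
                    "birth_year": int(b),
                    "death_age": int(round(a)),
                    "death_year": int(b + round(a)),
                    "birthplace_code": "LB" if f else "US-NY",
                }
                for b, f, a in zip(birth, fb, age)
            ]
        )

    def test_recovers_linear_shift(self):
        tab = fe_linear_check(self._linear_records(effect=2.0))
        assert tab.loc["foreign_born", "coef"] == pytest.approx(2.0, abs=0.3)

    def test_single_cohort_equals_plain_ols(self):
        import statsmodels.api as sm

        df = self._linear_records(seed=3, n=500, n_cohorts=1)
        tab = fe_linear_check(df)
        x = sm.add_constant((df["birthplace_code"] == "LB").astype(float))
        plain = sm.OLS(df["death_age"].astype(float), x).fit()
        assert tab.loc["foreign_born", "coef"] == pytest.approx(
            plain.params.iloc[1], abs=1e-8
        )

    def test_collinear_covariates_named(self):
        df = self._linear_records(n=200)
        df["foreign_born"] = (df["birthplace_code"] == "LB").astype(float)
        df["fb_copy"] = df["foreign_born"]
        with pytest.raises(ValueError, match="collinear"):
            fe_linear_check(df, covariate_columns=("foreign_born", "fb_copy"))

    def test_sign_agrees_with_gompertz_delta(self, mena_men_params):
        """Cross-estimator consistency: the FB linear coefficient has the
        same sign as delta-e65 from the truncated Gompertz fit."""
        x, z, lo, up, w = simulate_nativity_observations(mena_men_params, 8000, seed=13)
        m = GompertzProportionalHazards().fit(z, x, lower=lo, upper=up)
        eff = nativity_effect(m, 0, n_boot=50, seed=1)
        # rebuild a record frame from the same simulated arrays
        birth = (1996 - x).astype(int)  # mid-window proxy cohort
        df = make_records(
            [
                {
                    "birth_year": int(b),
                    "death_age": int(xi - 0.5),
                    "death_year": int(b + xi - 0.5),
                    "birthplace_code": "LB" if zz else "US-NY",
                }
                for b, xi, zz in zip(birth, x, z[:, 0])
            ]
        )
        tab = fe_linear_check(df)
        assert np.sign(tab.loc["foreign_born", "coef"]) == np.sign(eff["delta_e65"])
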