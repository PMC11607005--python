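"""Synthetic-cohort generator checks: determinism, mixtures, truncation."""

import numpy as np
import pandas as pd
import pytest

from namemort.gompertz import GompertzParams, survival
from namemort.synthetic import (
    SyntheticConfig,
    TruncationWindow,
    apply_truncation,
    default_gompertz_params,
    generate_cohort,
    generate_names,
    is_foreign_born,
    observation_windows,
    simulate_death_age,
)

from conftest import make_records


class TestNames:
    def test_fixed_seed_deterministic(self):
        a = generate_names("mena", 3, rng_seed=1)
        b = generate_names("mena", 3, rng_seed=1)
        assert a == b and len(a) == 3
        assert all(given and surname for given, surname in a)

    def test_empty_request(self):
        assert generate_names("white", 0, rng_seed=1) == []

    def test_unknown_group_named_in_error(self):
        with pytest.raises(ValueError, match="martian"):
            generate_names("martian", 5, rng_seed=1)

    def test_groups_differ_statistically(self):
        # distinct transition tensors should make bigram profiles diverge
        def bigram_counts(pairs):
            from collections import Counter

            c = Counter()
            for g, s in pairs:
                for w in (g, s):
                    c.update(w[i : i + 2] for i in range(len(w) - 1))
            total = sum(c.values())
            return {k: v / total for k, v in c.items()}

        mena = bigram_counts(generate_names("mena", 800, rng_seed=5))
        white = bigram_counts(generate_names("white", 800, rng_seed=6))
        keys = set(mena) | set(white)
        tv = 0.5 * sum(abs(mena.get(k, 0) - white.get(k, 0)) for k in keys)
        assert tv > 0.2


class TestConfigValidation:
    def test_bad_proportions(self):
        with pytest.raises(ValueError, match="sum"):
            SyntheticConfig(n_records=10, group_proportions={"white": 0.5, "mena": 0.4})

    def test_bad_fraction(self):
        with pytest.raises(ValueError, match="fraction"):
            SyntheticConfig(
                n_records=10, foreign_born_fraction_by_group={"white": 1.5, "api": 0.1,
                                                              "black": 0, "hispanic": 0,
                                                              "mena": 0, "other": 0}
            )

    def test_empty_cohort_range(self):
        with pytest.raises(ValueError, match="cohort_range"):
            SyntheticConfig(n_records=10, cohort_range=(1950, 1940))


class TestCohort:
    def test_reproducible_byte_identical(self):
        cfg = SyntheticConfig(n_records=1000, seed=7)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_foreign_born_fraction_near_target(self):
        # MENA-only cohort with the 0.61 foreign-born share
        cfg = SyntheticConfig(
            n_records=5000,
            seed=2,
            group_proportions={"mena": 1.0},
            include_names=False,
        )
        df = generate_cohort(cfg)
        frac = is_foreign_born(df["birthplace_code"]).mean()
        se = np.sqrt(0.61 * 0.39 / len(df))
        assert abs(frac - 0.61) < 4 * se

    def test_degenerate_mixture(self):
        cfg = SyntheticConfig(n_records=200, seed=1, group_proportions={"black": 1.0})
        df = generate_cohort(cfg)
        assert (df["group"] == "black").all()
        assert (df["race_code"] == "black").all()

    def test_death_year_age_consistency(self):
        df = generate_cohort(SyntheticConfig(n_records=3000, seed=9, include_names=False))
        drift = (df["death_year"] - df["birth_year"] - df["death_age"]).abs()
        assert drift.max() <= 1
        assert (df["death_age"] >= 0).all()
        assert (df["weight"] >= 0).all()

    def test_mena_race_codes_mostly_white(self):
        cfg = SyntheticConfig(
            n_records=4000, seed=4, group_proportions={"mena": 1.0}, include_names=False
        )
        df = generate_cohort(cfg)
        shares = df["race_code"].value_counts(normalize=True)
        assert shares["white"] == pytest.approx(0.85, abs=0.03)
        assert shares["api"] == pytest.approx(0.13, abs=0.03)

    def test_parent_fields_populated(self):
        df = generate_cohort(SyntheticConfig(n_records=300, seed=5))
        assert (df["mother_name"].str.contains(" ")).all()
        same = (df["father_surname"] == df["surname"]).mean()
        assert 0.88 < same < 1.0

    def test_race_report_years_span_1981(self):
        df = generate_cohort(SyntheticConfig(n_records=2000, seed=6, include_names=False))
        years = df["race_last_report_year"]
        assert (years < 1981).any() and (years >= 1981).any()


class TestTruncation:
    window = TruncationWindow()

    def test_below_window_dropped(self):
        df = make_records([{"death_year": 1987, "death_age": 70, "birth_year": 1917}])
        assert len(apply_truncation(df, self.window)) == 0

    def test_inclusive_boundaries_retained(self):
        df = make_records(
            [
                {"death_year": 1988, "death_age": 65, "birth_year": 1923},
                {"death_year": 2005, "death_age": 82, "birth_year": 1923},
            ]
        )
        assert len(apply_truncation(df, self.window)) == 2

    def test_age_floor(self):
        df = make_records([{"death_year": 1995, "death_age": 64, "birth_year": 1931}])
        assert len(apply_truncation(df, self.window)) == 0

    def test_pure_filter_semantics(self):
        df = generate_cohort(SyntheticConfig(n_records=500, seed=3, include_names=False))
        before = df.copy()
        kept = apply_truncation(df, self.window)
        pd.testing.assert_frame_equal(df, before)  # input untouched
        assert kept.index.is_monotonic_increasing
        assert set(kept.index) <= set(df.index)
        pd.testing.assert_frame_equal(kept, df.loc[kept.index])

    def test_truncated_distribution_matches_normalized_density(self, mena_men_params):
        """Retained death ages from a single cohort follow the doubly
        truncated density computed by numeric normalization."""
        p = mena_men_params
        rng = np.random.default_rng(42)
        n = 200_000
        ages = simulate_death_age(p, rng_seed=rng, size=n)
        lo, up = 73.0, 90.0  # cohort born 1915 under the 1988-2005 window
        kept = ages[(ages >= lo) & (ages <= up)]
        bins = np.arange(lo, up + 1.0)
        hist, _ = np.histogram(kept, bins=bins)
        emp = hist / kept.size
        s = survival(p, bins)
        expected = (s[:-1] - s[1:]) / (s[0] - s[-1])
        tv = 0.5 * np.abs(emp - expected).sum()
        assert tv < 0.01


class TestWindows:
    def test_observation_window_formula(self):
        lo, up = observation_windows([1915, 1930], TruncationWindow())
        assert lo[0] == pytest.approx(max(65.0, 1988 - 1915 - 0.5))
        assert up[0] == pytest.approx(2005 - 1915 + 0.5)
        assert lo[1] == 65.0  # age floor binds for late cohorts

    def test_simulated_observations_respect_windows(self, mena_men_params):
        from namemort.synthetic import simulate_nativity_observations

        x, z, lo, up, w = simulate_nativity_observations(mena_men_params, 5000, seed=2)
        assert np.all(x >= lo) and np.all(x <= up)
        assert np.all(lo >= 65.0)
        assert set(np.unique(z)) <= {0.0, 1.0}


class TestDeathAgeSimulation:
    def test_invalid_params_error(self):
        with pytest.raises(ValueError):
            simulate_death_age(GompertzParams(0.02, 0.09), covariates=[1.0, 2.0])

    def test_covariate_scaling(self):
        p = GompertzParams(0.02, 0.09, beta=[np.log(0.5)])
        protected = simulate_death_age(p, covariates=[1.0], size=20_000, rng_seed=1)
        baseline = simulate_death_age(p, covariates=[0.0], size=20_000, rng_seed=2)
        assert protected.mean() > baseline.mean()

    def test_default_conditions_calibrated(self):
        from namemort.gompertz import e65
        from namemort.synthetic import REFERENCE_CONDITIONS

        params = default_gompertz_params()
        for key, cond in REFERENCE_CONDITIONS.items():
            p = params[key]
            assert e65(p, method="closed_form") == pytest.approx(cond["e65_us"], abs=1e-6)
            assert np.exp(p.beta[0]) == pytest.approx(cond["hazard_ratio"], abs=1e-9)
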