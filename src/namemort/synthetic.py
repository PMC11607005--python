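"""Synthetic person-record cohorts with the structure the analysis assumes.

The generator emulates a social-security style death-record extract: six
ethno-racial groups crossed with nativity (foreign-born vs US-born), name
strings whose character statistics differ by group, Gompertz adult mortality
with group/nativity/sex-specific hazards measured from age 65, birth cohorts
spanning 1890-1940, and an observation window restricted to deaths in
1988-2005 at ages 65 and over.

Default mortality conditions are *calibrated*, not hard-coded: for each
(group, sex) cell the baseline (a0, b0) and the foreign-born log-hazard are
solved at run time so the model-implied conditional life expectancies match
the study's reference e65 values and hazard ratios (see
``REFERENCE_CONDITIONS``).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gompertz import GompertzParams, calibrate_from_e65, sample_death_age
from .names import NameGeneratorSpec, default_name_specs, generate_name_pairs

__all__ = [
    "GROUPS",
    "SEXES",
    "MENA_BIRTHPLACE_CODES",
    "REFERENCE_CONDITIONS",
    "TruncationWindow",
    "SyntheticConfig",
    "PersonRecord",
    "RECORD_COLUMNS",
    "default_gompertz_params",
    "is_foreign_born",
    "simulate_death_age",
    "generate_names",
    "generate_cohort",
    "apply_truncation",
    "observation_windows",
    "simulate_nativity_observations",
]

GROUPS = ["white", "api", "black", "hispanic", "mena", "other"]
SEXES = ["male", "female"]

# Reference study conditions per (group, sex): US-born e65, foreign-born e65,
# and the foreign-born/US-born hazard ratio.  These define the generator's
# default mortality regimes.
REFERENCE_CONDITIONS: dict[tuple[str, str], dict[str, float]] = {
    ("white", "male"): {"e65_us": 81.59, "e65_fb": 82.75, "hazard_ratio": 0.85},
    ("api", "male"): {"e65_us": 82.26, "e65_fb": 84.29, "hazard_ratio": 0.75},
    ("black", "male"): {"e65_us": 79.67, "e65_fb": 80.06, "hazard_ratio": 0.95},
    ("hispanic", "male"): {"e65_us": 82.07, "e65_fb": 84.50, "hazard_ratio": 0.72},
    ("mena", "male"): {"e65_us": 82.26, "e65_fb": 85.39, "hazard_ratio": 0.64},
    ("other", "male"): {"e65_us": 80.13, "e65_fb": 80.06, "hazard_ratio": 1.01},
    ("white", "female"): {"e65_us": 86.60, "e65_fb": 87.46, "hazard_ratio": 0.88},
    ("api", "female"): {"e65_us": 87.34, "e65_fb": 88.22, "hazard_ratio": 0.88},
    ("black", "female"): {"e65_us": 85.25, "e65_fb": 88.64, "hazard_ratio": 0.65},
    ("hispanic", "female"): {"e65_us": 87.05, "e65_fb": 89.65, "hazard_ratio": 0.67},
    ("mena", "female"): {"e65_us": 86.42, "e65_fb": 88.66, "hazard_ratio": 0.71},
    ("other", "female"): {"e65_us": 85.18, "e65_fb": 84.19, "hazard_ratio": 1.14},
}

# group mix and foreign-born shares of the over-65 reference sample
DEFAULT_GROUP_PROPORTIONS = {
    "white": 0.727,
    "api": 0.035,
    "black": 0.170,
    "hispanic": 0.055,
    "mena": 0.0065,
    "other": 0.0065,
}
DEFAULT_FOREIGN_BORN_FRACTION = {
    "white": 0.064,
    "api": 0.74,
    "black": 0.030,
    "hispanic": 0.54,
    "mena": 0.61,
    "other": 0.11,
}

_FOREIGN_CODES = {
    "mena": ["LB", "SY", "IR", "IQ", "EG", "MA", "DZ", "JO", "PS", "YE", "SA", "TN"],
    "white": ["IT", "DE", "GB", "IE", "PL", "RU", "GR", "SE"],
    "api": ["CN", "JP", "PH", "KR", "IN", "VN"],
    "black": ["JM", "HT", "NG", "TT", "BB"],
    "hispanic": ["MX", "CU", "DO", "SV", "GT", "CO"],
    "other": ["BR", "FJ", "GY", "ZZ"],
}
MENA_BIRTHPLACE_CODES = frozenset(_FOREIGN_CODES["mena"])

_US_STATES = [
    "NY", "CA", "PA", "IL", "OH", "TX", "MI", "MA", "NJ", "MO",
    "NC", "GA", "VA", "TN", "AL", "MN", "WI", "FL", "KY", "IA",
]

RECORD_COLUMNS = [
    "record_id", "given_name", "surname", "father_surname", "mother_name",
    "sex", "birth_year", "death_year", "death_age", "birthplace_code",
    "race_code", "race_last_report_year", "weight", "group",
]


@dataclass(frozen=True)
class TruncationWindow:
    """Observability window: calendar death-year bounds (inclusive) and a
    minimum recorded age at death."""

    death_year_min: int = 1988
    death_year_max: int = 2005
    min_death_age: int = 65

    def __post_init__(self) -> None:
        if self.death_year_min > self.death_year_max:
            raise ValueError("death_year_min must not exceed death_year_max")
        if self.min_death_age < 0:
            raise ValueError("min_death_age must be nonnegative")


@dataclass
class PersonRecord:
    """One individual's record; the cohort container is a DataFrame with the
    same fields as columns (see ``RECORD_COLUMNS``)."""

    record_id: str
    given_name: str
    surname: str
    father_surname: str
    mother_name: str
    sex: str
    birth_year: int
    death_year: int
    death_age: int
    birthplace_code: str
    race_code: str
    race_last_report_year: int
    weight: float = 1.0
    group: str = ""


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic cohort generator.

    All randomness flows from ``seed``; the same config generates a
    byte-identical cohort on every run and platform.
    """

    n_records: int = 10_000
    seed: int = 0
    group_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS)
    )
    foreign_born_fraction_by_group: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOREIGN_BORN_FRACTION)
    )
    cohort_range: tuple[int, int] = (1890, 1940)
    gompertz_by_group: dict[tuple[str, str], GompertzParams] | None = None
    name_specs: dict[str, NameGeneratorSpec] | None = None
    perturb_rate: float = 0.05
    window: TruncationWindow = field(default_factory=TruncationWindow)
    birth_year_weights: dict[int, float] | None = None
    father_same_surname_prob: float = 0.95
    include_names: bool = True

    def __post_init__(self) -> None:
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group proportions sum to {total}, not 1")
        for g, p in self.group_proportions.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"proportion for {g!r} outside [0, 1]")
        for g, p in self.foreign_born_fraction_by_group.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"foreign-born fraction for {g!r} outside [0, 1]")
        if self.cohort_range[0] > self.cohort_range[1]:
            raise ValueError("cohort_range is empty")
        if self.n_records < 0:
            raise ValueError("n_records must be nonnegative")


@functools.lru_cache(maxsize=4)
def _default_gompertz_cached(age_origin: float) -> dict[tuple[str, str], GompertzParams]:
    return {
        key: calibrate_from_e65(
            cond["e65_us"], cond["e65_fb"], cond["hazard_ratio"], age_origin=age_origin
        )
        for key, cond in REFERENCE_CONDITIONS.items()
    }


def default_gompertz_params(age_origin: float = 65.0) -> dict[tuple[str, str], GompertzParams]:
    """Per-(group, sex) Gompertz parameters calibrated to the reference e65
    table; ``beta[0]`` is the foreign-born log hazard ratio."""
    return dict(_default_gompertz_cached(age_origin))


def is_foreign_born(birthplace_code) -> np.ndarray:
    """Foreign-born indicator: birthplace codes not starting with 'US'."""
    codes = pd.Series(birthplace_code, dtype="string").fillna("")
    return ~codes.str.startswith("US").to_numpy(dtype=bool)


def simulate_death_age(
    params: GompertzParams, covariates=None, age_origin: float | None = None, rng_seed=None,
    size=None,
):
    """Draw death age(s) from the proportional-hazard Gompertz model.

    ``covariates`` (Z vector) enters through ``exp(beta . Z)``; the draw is
    inverse-CDF so a fixed seed is fully reproducible.
    """
    if age_origin is not None and age_origin != params.age_origin:
        params = GompertzParams(params.a0, params.b0, params.beta, age_origin)
    lp = 0.0
    if covariates is not None:
        lp = params.linear_predictor(covariates)
        if np.ndim(covariates) <= 1:
            lp = float(lp[0])
    return sample_death_age(params, lin_pred=lp, size=size, rng=rng_seed)


def generate_names(group: str, n: int, rng_seed, specs=None, perturb_rate: float = 0.05):
    """``n`` (given_name, surname) pairs from the named group's generator."""
    specs = specs if specs is not None else default_name_specs(0, perturb_rate=perturb_rate)
    if group not in specs:
        raise ValueError(f"unknown group {group!r}; known groups: {sorted(specs)}")
    return generate_name_pairs(specs[group], n, rng_seed)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a full (untruncated) synthetic cohort as a DataFrame.

    Death ages are drawn continuously from the (group, sex)-specific Gompertz
    model measured from the window's minimum death age, then recorded as
    completed integer years; the death year adds a Bernoulli draw on the
    fractional year so that death_year - birth_year stays within one year of
    the recorded age, as in administrative data.
    """
    n = config.n_records
    ss_assign, ss_mort, ss_names, ss_admin = np.random.SeedSequence(config.seed).spawn(4)
    rng_assign = np.random.default_rng(ss_assign)
    rng_admin = np.random.default_rng(ss_admin)

    groups = list(config.group_proportions)
    probs = np.array([config.group_proportions[g] for g in groups], dtype=float)
    group_idx = rng_assign.choice(len(groups), size=n, p=probs / probs.sum())
    group = np.array(groups, dtype=object)[group_idx]
    sex = np.where(rng_assign.random(n) < 0.5, "male", "female").astype(object)
    fb_frac = np.array(
        [config.foreign_born_fraction_by_group.get(g, 0.0) for g in groups]
    )[group_idx]
    foreign_born = rng_assign.random(n) < fb_frac

    if config.birth_year_weights:
        years = np.array(sorted(config.birth_year_weights), dtype=int)
        w = np.array([config.birth_year_weights[y] for y in years], dtype=float)
        birth_year = rng_assign.choice(years, size=n, p=w / w.sum())
    else:
        lo, hi = config.cohort_range
        birth_year = rng_assign.integers(lo, hi + 1, size=n)

    gparams = config.gompertz_by_group or default_gompertz_params(
        float(config.window.min_death_age)
    )
    rng_mort = np.random.default_rng(ss_mort)
    death_age_cont = np.empty(n, dtype=float)
    for g in groups:
        for s in SEXES:
            mask = (group == g) & (sex == s)
            if not mask.any():
                continue
            p = gparams[(g, s)]
            lp = (p.beta[0] if p.beta.size else 0.0) * foreign_born[mask]
            death_age_cont[mask] = sample_death_age(
                p, lin_pred=lp, size=int(mask.sum()), rng=rng_mort
            )

    death_age = np.floor(death_age_cont).astype(int)
    frac = death_age_cont - death_age
    death_year = birth_year + death_age + (rng_admin.random(n) < frac).astype(int)

    given = np.full(n, "", dtype=object)
    surname = np.full(n, "", dtype=object)
    father_surname = np.full(n, "", dtype=object)
    mother_name = np.full(n, "", dtype=object)
    if config.include_names:
        specs = config.name_specs or default_name_specs(
            _child_seed(ss_names), perturb_rate=config.perturb_rate
        )
        name_seeds = ss_names.spawn(len(groups))
        for g, g_ss in zip(groups, name_seeds):
            idx = np.flatnonzero(group == g)
            if idx.size == 0:
                continue
            spec = specs[g]
            # child + mother + spare father surnames, one stream per group
            pairs = generate_name_pairs(spec, 3 * idx.size, _child_seed(g_ss))
            child = pairs[: idx.size]
            mother = pairs[idx.size : 2 * idx.size]
            spare = pairs[2 * idx.size :]
            given[idx] = [p[0] for p in child]
            surname[idx] = [p[1] for p in child]
            mother_name[idx] = [f"{p[0]} {p[1]}" for p in mother]
            same = rng_admin.random(idx.size) < config.father_same_surname_prob
            father_surname[idx] = np.where(
                same, [p[1] for p in child], [p[1] for p in spare]
            )

    birthplace = np.empty(n, dtype=object)
    race_code = np.empty(n, dtype=object)
    for i_g, g in enumerate(groups):
        mask = group_idx == i_g
        m = int(mask.sum())
        if m == 0:
            continue
        fcodes = _FOREIGN_CODES.get(g, ["ZZ"])
        fpick = rng_admin.choice(len(fcodes), size=m)
        upick = rng_admin.choice(len(_US_STATES), size=m)
        birthplace[mask] = np.where(
            foreign_born[mask],
            np.array(fcodes, dtype=object)[fpick],
            np.array(["US-" + s for s in _US_STATES], dtype=object)[upick],
        )
        if g == "mena":
            # MENA ancestry is not separately coded: mostly filed as white,
            # some as Asian/Pacific Islander
            race_code[mask] = rng_admin.choice(
                np.array(["white", "api", "other"], dtype=object),
                size=m,
                p=[0.85, 0.13, 0.02],
            )
        else:
            race_code[mask] = g

    race_last_report_year = rng_admin.integers(1972, 2001, size=n)

    return pd.DataFrame(
        {
            "record_id": [f"R{i:07d}" for i in range(n)],
            "given_name": given,
            "surname": surname,
            "father_surname": father_surname,
            "mother_name": mother_name,
            "sex": sex,
            "birth_year": birth_year,
            "death_year": death_year,
            "death_age": death_age,
            "birthplace_code": birthplace,
            "race_code": race_code,
            "race_last_report_year": race_last_report_year,
            "weight": np.ones(n),
            "group": group,
        }
    )


def apply_truncation(records: pd.DataFrame, window: TruncationWindow) -> pd.DataFrame:
    """Keep records observable in the window (pure filter, order preserved).

    A record is retained iff death_year lies in the inclusive calendar window
    and the recorded death age is at least the window's minimum.
    """
    mask = (
        (records["death_year"] >= window.death_year_min)
        & (records["death_year"] <= window.death_year_max)
        & (records["death_age"] >= window.min_death_age)
    )
    return records.loc[mask].copy()


def observation_windows(birth_year, window: TruncationWindow, age_origin: float = 65.0):
    """Per-record observable age bounds [L, U] implied by birth year.

    With deaths observable only in the calendar window and at ages >=
    ``min_death_age``, a person born in year c can only be seen dying between
    L = max(origin, year_min - c - 0.5) and U = year_max - c + 0.5; the
    half-year shifts match the mid-year continuity correction applied to
    integer recorded ages.
    """
    by = np.asarray(birth_year, dtype=float)
    lower = np.maximum(age_origin, window.death_year_min - by - 0.5)
    upper = window.death_year_max - by + 0.5
    return lower, upper


def simulate_nativity_observations(
    params: GompertzParams,
    n_per_group: int,
    cohort_range: tuple[int, int] = (1890, 1940),
    window: TruncationWindow | None = None,
    seed=0,
):
    """Fast two-nativity-group mortality simulation (no names).

    Simulates ``n_per_group`` US-born (Z=0) and ``n_per_group`` foreign-born
    (Z=1) individuals under ``params`` (whose ``beta[0]`` is the foreign-born
    log hazard ratio), applies administrative rounding and the truncation
    window, and returns the fitting arrays
    ``(x, Z, lower, upper, weight)`` with the mid-year continuity correction
    already applied to x.
    """
    window = window or TruncationWindow()
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    z = np.repeat([0.0, 1.0], n_per_group)
    lo, hi = cohort_range
    birth_year = rng.integers(lo, hi + 1, size=n)
    lp = (params.beta[0] if params.beta.size else 0.0) * z
    cont = sample_death_age(params, lin_pred=lp, size=n, rng=rng)
    death_age = np.floor(cont).astype(int)
    death_year = birth_year + death_age + (rng.random(n) < (cont - death_age)).astype(int)
    keep = (
        (death_year >= window.death_year_min)
        & (death_year <= window.death_year_max)
        & (death_age >= window.min_death_age)
    )
    x = death_age[keep] + 0.5
    lower, upper = observation_windows(birth_year[keep], window, params.age_origin)
    return x, z[keep].reshape(-1, 1), lower, upper, np.ones(keep.sum())
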