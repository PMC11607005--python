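"""Reading and writing person-record CSVs and run configuration files.

The record CSV is headered UTF-8, comma-separated, strings quoted as needed;
one row per individual with the documented column set.  Filtering rules
(truncation, training-set exclusions) are *not* applied at I/O time — files
round-trip intact and every exclusion happens in the stage that owns it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .synthetic import SyntheticConfig, TruncationWindow

__all__ = ["REQUIRED_COLUMNS", "read_records", "write_records",
           "synthetic_config_to_dict", "synthetic_config_from_dict",
           "load_config_file"]

REQUIRED_COLUMNS = [
    "record_id", "given_name", "surname", "father_surname", "mother_name",
    "sex", "birth_year", "death_year", "death_age", "birthplace_code",
    "race_code", "race_last_report_year", "weight",
]

_STRING_COLUMNS = [
    "record_id", "given_name", "surname", "father_surname", "mother_name",
    "sex", "birthplace_code", "race_code",
]
_INT_COLUMNS = ["birth_year", "death_year", "death_age", "race_last_report_year"]


def read_records(path) -> pd.DataFrame:
    """Load a person-record CSV, validating columns and basic invariants."""
    df = pd.read_csv(path, dtype={c: str for c in _STRING_COLUMNS}, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"record file {path} is missing required column(s): {missing}; "
            f"expected at least {REQUIRED_COLUMNS}"
        )
    for c in _INT_COLUMNS:
        df[c] = pd.to_numeric(df[c], errors="raise").astype(int)
    df["weight"] = pd.to_numeric(df["weight"], errors="raise").astype(float)
    if (df["weight"] < 0).any():
        raise ValueError("negative weights found; weights must be nonnegative")
    if (df["death_age"] < 0).any():
        raise ValueError("negative death_age found")
    drift = (df["death_year"] - df["birth_year"] - df["death_age"]).abs()
    if (drift > 1).any():
        bad = df.index[drift > 1][0]
        raise ValueError(
            f"row {bad}: death_year - birth_year differs from death_age by more "
            "than one year (administrative-rounding invariant violated)"
        )
    return df


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def _window_to_dict(w: TruncationWindow) -> dict:
    return {
        "death_year_min": w.death_year_min,
        "death_year_max": w.death_year_max,
        "min_death_age": w.min_death_age,
    }


def synthetic_config_to_dict(cfg: SyntheticConfig) -> dict:
    """Serializable view of a SyntheticConfig (simple fields only; the
    Gompertz and name-generator specifications regenerate from the seed and
    the built-in calibration unless set programmatically)."""
    return {
        "n_records": cfg.n_records,
        "seed": cfg.seed,
        "group_proportions": dict(cfg.group_proportions),
        "foreign_born_fraction_by_group": dict(cfg.foreign_born_fraction_by_group),
        "cohort_range": list(cfg.cohort_range),
        "perturb_rate": cfg.perturb_rate,
        "window": _window_to_dict(cfg.window),
        "birth_year_weights": (
            {int(k): float(v) for k, v in cfg.birth_year_weights.items()}
            if cfg.birth_year_weights
            else None
        ),
        "father_same_surname_prob": cfg.father_same_surname_prob,
        "include_names": cfg.include_names,
    }


def synthetic_config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    if "window" in d and isinstance(d["window"], dict):
        d["window"] = TruncationWindow(**d["window"])
    if "cohort_range" in d:
        d["cohort_range"] = tuple(d["cohort_range"])
    known = set(SyntheticConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown synthetic-config keys: {sorted(unknown)}")
    return SyntheticConfig(**d)


def load_config_file(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) configuration file to a dict."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data
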