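import numpy as np
import pandas as pd
import pytest

from namemort import (
    GompertzParams,
    calibrate_from_e65,
    generate_names,
    train_name_classifier,
)


@pytest.fixture(scope="session")
def mena_men_params() -> GompertzParams:
    """Gompertz parameters calibrated to the MENA-men reference conditions
    (US-born e65 = 82.26, foreign-born e65 = 85.39, hazard ratio 0.64)."""
    return calibrate_from_e65(82.26, 85.39, 0.64)


@pytest.fixture(scope="session")
def separable_corpus():
    """Names from two well-separated character processes, labelled 1 = MENA-like."""
    n = 1500
    pos = [f"{g} {s}" for g, s in generate_names("mena", n, rng_seed=1)]
    neg = [f"{g} {s}" for g, s in generate_names("white", n, rng_seed=2)]
    return pos + neg, np.array([1] * n + [0] * n)


@pytest.fixture(scope="session")
def trained_separable(separable_corpus):
    names, labels = separable_corpus
    clf, metrics = train_name_classifier(names, labels, seed=0)
    return clf, metrics, names, labels


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a small record frame with sensible defaults per row."""
    defaults = {
        "record_id": "R0",
        "given_name": "khalil",
        "surname": "haddad",
        "father_surname": "haddad",
        "mother_name": "amira khoury",
        "sex": "male",
        "birth_year": 1920,
        "death_year": 1995,
        "death_age": 75,
        "birthplace_code": "LB",
        "race_code": "white",
        "race_last_report_year": 1990,
        "weight": 1.0,
        "group": "mena",
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["record_id"] = f"R{i:07d}"
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)
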