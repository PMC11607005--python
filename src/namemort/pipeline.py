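"""End-to-end orchestration: records -> classifier -> group assignment ->
truncation -> descriptive and fitted mortality tables.

Stage order: load or generate records; build the birthplace-labelled training
set; train the name classifier; score every record and reassign group = MENA
where the classifier (or a MENA birthplace) says so, recording which groups
those records were previously coded under; apply the truncation window; then
emit the descriptive table, the per-group/sex hazard-ratio and e65 tables,
and the fixed-effects linear robustness table.  Every stage logs record
counts in and out, and every written artifact carries the config hash and
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import NameEthnicityClassifier, build_training_set, train_name_classifier
from .io import read_records, synthetic_config_to_dict, write_records
from .mortality import descriptive_stats, fe_linear_check, fit_group_nativity_tables
from .synthetic import (
    MENA_BIRTHPLACE_CODES,
    SyntheticConfig,
    TruncationWindow,
    apply_truncation,
    generate_cohort,
    is_foreign_born,
)

__all__ = ["PipelineConfig", "run_pipeline", "write_tables", "assign_groups",
           "plot_death_age_histograms"]

logger = logging.getLogger("namemort.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of the full analysis run (exactly one input mode)."""

    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    use_classifier: bool = True
    classifier_params: dict = field(default_factory=dict)
    test_size: float = 0.2
    mena_birthplace_codes: frozenset = MENA_BIRTHPLACE_CODES
    window: TruncationWindow = field(default_factory=TruncationWindow)
    union_with_birthplace: bool = True
    min_cell: int = 50
    n_boot: int = 1000
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_csv / synthetic must be set")

    def hash(self) -> str:
        payload = {
            "input_csv": self.input_csv,
            "synthetic": synthetic_config_to_dict(self.synthetic) if self.synthetic else None,
            "use_classifier": self.use_classifier,
            "classifier_params": self.classifier_params,
            "test_size": self.test_size,
            "mena_birthplace_codes": sorted(self.mena_birthplace_codes),
            "window": [self.window.death_year_min, self.window.death_year_max,
                       self.window.min_death_age],
            "union_with_birthplace": self.union_with_birthplace,
            "min_cell": self.min_cell,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def assign_groups(
    records: pd.DataFrame,
    scores: np.ndarray | None,
    threshold: float,
    mena_codes,
    union_with_birthplace: bool = True,
) -> tuple[pd.Series, pd.Series]:
    """Classifier-overrides-prior-coding group assignment.

    A record is assigned to the MENA group when its name score clears the
    threshold (and, if ``union_with_birthplace``, also when its birthplace is
    in a MENA country); otherwise it keeps its coded race group.  Returns the
    assignment and the share of prior codes among reassigned records.
    """
    mena_mask = pd.Series(False, index=records.index)
    if scores is not None:
        mena_mask |= pd.Series(np.asarray(scores) >= threshold, index=records.index)
    if union_with_birthplace:
        mena_mask |= records["birthplace_code"].isin(set(mena_codes))
    assigned = records["race_code"].where(~mena_mask, "mena")
    prior = records.loc[mena_mask, "race_code"]
    shares = (
        prior.value_counts(normalize=True)
        if len(prior)
        else pd.Series(dtype=float)
    )
    return assigned.rename("assigned_group"), shares.rename("share")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the artifact bundle as a dict."""
    logging.basicConfig(level=config.log_level)
    counts: dict[str, int] = {}
    bundle: dict = {"config_hash": config.hash(), "seed": config.seed}

    # stage 1: load or generate ------------------------------------------
    if config.synthetic is not None:
        records = generate_cohort(config.synthetic)
        logger.info("generated %d synthetic records", len(records))
    else:
        records = read_records(config.input_csv)
        logger.info("loaded %d records from %s", len(records), config.input_csv)
    counts["input"] = len(records)

    # stage 2-3: training set + classifier --------------------------------
    clf = None
    metrics = None
    scores = None
    if config.use_classifier:
        training = build_training_set(records, config.mena_birthplace_codes)
        counts["training_names"] = len(training)
        counts["training_positive"] = int(training["label"].sum())
        logger.info(
            "training set: %d names, %d positive",
            counts["training_names"], counts["training_positive"],
        )
        clf, metrics = train_name_classifier(
            training["name"],
            training["label"],
            test_size=config.test_size,
            seed=config.seed,
            **config.classifier_params,
        )
        logger.info(
            "classifier held-out metrics: P=%.3f R=%.3f F1=%.3f (n=%d)",
            metrics.precision, metrics.recall, metrics.f1, metrics.n_test,
        )
        full_names = (records["given_name"] + " " + records["surname"]).str.strip()
        scores = clf.decision_scores(full_names)
        assigned, prior_shares = assign_groups(
            records, scores, clf.threshold, config.mena_birthplace_codes,
            config.union_with_birthplace,
        )
    else:
        if "group" not in records.columns:
            raise ValueError("use_classifier=False requires a ground-truth 'group' column")
        assigned = records["group"].rename("assigned_group")
        prior_shares = pd.Series(dtype=float)
    records = records.assign(assigned_group=assigned)
    counts["assigned_mena"] = int((assigned == "mena").sum())
    logger.info("assigned %d records to the MENA group", counts["assigned_mena"])

    # stage 4: truncation --------------------------------------------------
    analysis = apply_truncation(records, config.window)
    counts["truncated"] = len(analysis)
    logger.info("truncation window retained %d of %d records", len(analysis), len(records))

    # stage 5: descriptive table ------------------------------------------
    table1 = descriptive_stats(analysis, by=("assigned_group", "sex", "nativity"))

    # stage 6: per-group/sex truncated Gompertz fits ----------------------
    table2, table3, fits = fit_group_nativity_tables(
        analysis,
        window=config.window,
        group_column="assigned_group",
        min_cell=config.min_cell,
        n_boot=config.n_boot,
        seed=config.seed,
    )

    # stage 7: fixed-effects linear robustness table ----------------------
    fe_rows = []
    for (group, sex), cell in analysis.groupby(["assigned_group", "sex"], sort=True):
        fb = is_foreign_born(cell["birthplace_code"])
        if fb.sum() < config.min_cell or (~fb).sum() < config.min_cell:
            continue
        tab = fe_linear_check(cell)
        row = tab.loc["foreign_born"]
        fe_rows.append(
            {"group": group, "sex": sex, "coef_foreign_born": row["coef"],
             "se": row["se"], "lower": row["lower"], "upper": row["upper"],
             "n": len(cell)}
        )
    appendix_fe = pd.DataFrame(fe_rows)

    bundle.update(
        {
            "records": records,
            "analysis": analysis,
            "classifier": clf,
            "classifier_metrics": metrics,
            "scores": scores,
            "prior_shares": prior_shares,
            "table1": table1,
            "table2": table2,
            "table3": table3,
            "appendix_fe": appendix_fe,
            "fits": fits,
            "counts": counts,
        }
    )
    if config.out_dir is not None:
        write_tables(bundle, config.out_dir)
    return bundle


def _write_stamped(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, index=False)


def write_tables(bundle: dict, out_dir) -> list[str]:
    """Write the artifact bundle's tables/files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={bundle['config_hash']} seed={bundle['seed']}"
    written = []
    for name in ("table1", "table2", "table3", "appendix_fe"):
        path = out / f"{name}.csv"
        _write_stamped(bundle[name], path, stamp)
        written.append(str(path))
    metrics = bundle.get("classifier_metrics")
    if metrics is not None:
        path = out / "classifier_metrics.csv"
        _write_stamped(pd.DataFrame([metrics.as_dict()]), path, stamp)
        written.append(str(path))
    clf = bundle.get("classifier")
    if clf is not None:
        clf.save(out / "name_model.npz")
        clf.vocab_.save(out / "bpe_vocab.txt")
        written += [str(out / "name_model.npz"), str(out / "bpe_vocab.txt")]
    manifest = {
        "config_hash": bundle["config_hash"],
        "seed": bundle["seed"],
        "counts": bundle["counts"],
        "prior_shares": bundle["prior_shares"].to_dict(),
        "files": written,
    }
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    written.append(str(out / "run_manifest.json"))
    return written


def plot_death_age_histograms(records: pd.DataFrame, path, group_column="assigned_group"):
    """Basic per-group death-age histogram panel (descriptive figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted(records[group_column].unique())
    fig, axes = plt.subplots(
        nrows=(len(groups) + 2) // 3, ncols=3, figsize=(11, 2.6 * ((len(groups) + 2) // 3)),
        squeeze=False,
    )
    for ax, g in zip(axes.ravel(), groups):
        sub = records.loc[records[group_column] == g, "death_age"]
        ax.hist(sub, bins=range(60, 111), color="steelblue")
        ax.set_title(g)
        ax.set_xlabel("age at death")
    for ax in axes.ravel()[len(groups):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
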