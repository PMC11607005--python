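"""Probabilistic MENA-name classification.

``NameEthnicityClassifier`` is a scikit-learn style estimator: it learns a BPE
vocabulary on the training names, encodes each full name as a token-id
sequence, and trains a gated recurrent (LSTM) network to output the
probability that a name is of Middle Eastern / North African origin.
Training labels come from birthplace, not self-identified race: the training
set is the foreign-born subset, labelled positive when born in a MENA
country, with parents' names added under the child's label and records whose
last racial-identity report predates 1981 excluded (the earlier three-category
coding cannot distinguish the groups of interest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from ._lstm import TinyLSTM
from .bpe import BPEVocab, UNK
from .synthetic import is_foreign_born

__all__ = [
    "NameEthnicityClassifier",
    "ClassifierMetrics",
    "build_training_set",
    "train_name_classifier",
    "evaluate_scores",
    "threshold_sweep",
    "bigram_logistic_baseline",
]


@dataclass
class ClassifierMetrics:
    """Precision/recall/F1 at a decision threshold.

    When a denominator is zero the metric is reported as 0.0 and the
    corresponding ``*_defined`` flag is False.
    """

    precision: float
    recall: float
    f1: float
    n_test: int
    threshold: float
    precision_defined: bool = True
    recall_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_test": self.n_test,
            "threshold": self.threshold,
        }


def evaluate_scores(y_true, scores, threshold: float = 0.5) -> ClassifierMetrics:
    """Metrics for probability scores at a threshold (predict 1 iff p >= t)."""
    y = np.asarray(y_true, dtype=int)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    p_def, r_def = (tp + fp) > 0, (tp + fn) > 0
    precision = tp / (tp + fp) if p_def else 0.0
    recall = tp / (tp + fn) if r_def else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return ClassifierMetrics(precision, recall, f1, int(y.size), threshold, p_def, r_def)


def threshold_sweep(y_true, scores, thresholds=None) -> pd.DataFrame:
    """Precision/recall/F1 across decision thresholds (for threshold choice)."""
    if thresholds is None:
        thresholds = np.linspace(0.05, 0.95, 19)
    rows = []
    for t in thresholds:
        m = evaluate_scores(y_true, scores, t)
        rows.append({"threshold": t, "precision": m.precision, "recall": m.recall, "f1": m.f1})
    return pd.DataFrame(rows)


def build_training_set(records: pd.DataFrame, mena_birthplace_codes) -> pd.DataFrame:
    """Labelled (name, label) training pairs per the training-set rules.

    1. keep foreign-born records only; 2. label positive iff the birthplace
    code is in ``mena_birthplace_codes``; 3. drop records whose last
    racial-identity report predates 1981; 4. add each record's mother and
    father names under the child's label.  Duplicates are retained.
    """
    codes = set(mena_birthplace_codes)
    fb = records.loc[is_foreign_born(records["birthplace_code"])]
    kept = fb.loc[fb["race_last_report_year"] >= 1981]
    if len(kept) == 0:
        raise ValueError(
            "training set is empty after the foreign-born and pre-1981 "
            "exclusions; provide a larger input"
        )
    label = kept["birthplace_code"].isin(codes).astype(int)
    rows = []
    for (_, rec), lab in zip(kept.iterrows(), label):
        full = f"{rec['given_name']} {rec['surname']}".strip()
        rows.append((full, lab))
        for parent in (rec["mother_name"], rec["father_surname"]):
            parent = str(parent).strip()
            if parent:
                rows.append((parent, lab))
    return pd.DataFrame(rows, columns=["name", "label"])


class NameEthnicityClassifier(BaseEstimator, ClassifierMixin):
    """BPE + LSTM binary name classifier (scikit-learn interface).

    Parameters are the architecture and training knobs: BPE vocabulary cap,
    embedding and hidden sizes, epochs/batch/learning rate, the decision
    threshold applied by ``predict``, optional 'balanced' inverse-frequency
    class weighting, and the seed controlling initialization and batch order.
    """

    def __init__(
        self,
        max_vocab: int = 512,
        embedding_dim: int = 32,
        hidden_dim: int = 64,
        n_epochs: int = 10,
        batch_size: int = 256,
        learning_rate: float = 0.01,
        threshold: float = 0.5,
        class_weight=None,
        random_state: int = 0,
    ):
        self.max_vocab = max_vocab
        self.embedding_dim = embedding_dim
        self.hidden_dim = hidden_dim
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.class_weight = class_weight
        self.random_state = random_state

    def _encode(self, names) -> list[np.ndarray]:
        unk = self.token_to_id_[UNK]
        return [
            np.array(
                [self.token_to_id_.get(t, unk) for t in self.vocab_.tokenize(n)],
                dtype=np.int64,
            )
            for n in names
        ]

    def fit(self, X, y):
        """Learn the BPE vocabulary on X and train the recurrent network."""
        names = list(X)
        y = np.asarray(y, dtype=int)
        if len(names) != y.size:
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class; need both")
        if not set(classes) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.classes_ = np.array([0, 1])
        self.vocab_ = BPEVocab.learn(names, max_vocab=self.max_vocab)
        self.token_to_id_ = self.vocab_.token_ids()
        seqs = self._encode(names)
        cw = None
        if self.class_weight == "balanced":
            pos = y.mean()
            cw = {1: 0.5 / max(pos, 1e-12), 0: 0.5 / max(1 - pos, 1e-12)}
        elif isinstance(self.class_weight, dict):
            cw = self.class_weight
        self.net_ = TinyLSTM(
            vocab_size=len(self.token_to_id_),
            embedding_dim=self.embedding_dim,
            hidden_dim=self.hidden_dim,
            seed=self.random_state,
        )
        self.loss_trace_ = self.net_.fit(
            seqs,
            y,
            epochs=self.n_epochs,
            batch_size=self.batch_size,
            lr=self.learning_rate,
            class_weight=cw,
            seed=self.random_state + 1,
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        """(n, 2) array of [P(non-MENA), P(MENA)] per name."""
        if not hasattr(self, "net_"):
            raise RuntimeError("classifier is not fitted")
        p1 = self.net_.predict_proba(self._encode(list(X)))
        return np.column_stack([1.0 - p1, p1])

    def decision_scores(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold).astype(int)

    def evaluate(self, X, y, threshold: float | None = None) -> ClassifierMetrics:
        t = self.threshold if threshold is None else threshold
        return evaluate_scores(y, self.decision_scores(X), t)

    # -- single-file persistence ------------------------------------------
    def save(self, path) -> None:
        """Serialize weights + vocabulary + settings to one .npz file."""
        if not hasattr(self, "net_"):
            raise RuntimeError("classifier is not fitted")
        meta = {
            "params": self.get_params(),
            "merges": self.vocab_.merges,
            "alphabet": self.vocab_.alphabet,
            "max_vocab": self.vocab_.max_vocab,
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.net_.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "NameEthnicityClassifier":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        params = meta["params"]
        if isinstance(params.get("class_weight"), list):
            params["class_weight"] = None
        clf = cls(**params)
        clf.vocab_ = BPEVocab(
            merges=[tuple(m) for m in meta["merges"]],
            alphabet=list(meta["alphabet"]),
            max_vocab=int(meta["max_vocab"]),
        )
        clf.token_to_id_ = clf.vocab_.token_ids()
        clf.classes_ = np.array([0, 1])
        clf.net_ = TinyLSTM(len(clf.token_to_id_), clf.embedding_dim, clf.hidden_dim)
        clf.net_.load_state_dict({k: data[k] for k in ("E", "W", "b", "w_out", "b_out")})
        return clf


def train_name_classifier(
    names,
    labels,
    test_size: float = 0.2,
    seed: int = 0,
    **clf_params,
) -> tuple[NameEthnicityClassifier, ClassifierMetrics]:
    """Stratified split, fit, and held-out evaluation in one call."""
    names = list(names)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("need both classes present to train")
    x_tr, x_te, y_tr, y_te = train_test_split(
        names, labels, test_size=test_size, stratify=labels, random_state=seed
    )
    clf = NameEthnicityClassifier(random_state=seed, **clf_params)
    clf.fit(x_tr, y_tr)
    return clf, clf.evaluate(x_te, y_te)


def bigram_logistic_baseline(
    train_names, train_labels, test_names, test_labels, threshold: float = 0.5
) -> ClassifierMetrics:
    """Bag-of-character-bigrams logistic regression, the sanity oracle the
    sequence model must not materially underperform."""
    from sklearn.feature_extraction.text import CountVectorizer
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline

    pipe = make_pipeline(
        CountVectorizer(analyzer="char", ngram_range=(1, 2), lowercase=True),
        LogisticRegression(max_iter=2000),
    )
    pipe.fit(list(train_names), np.asarray(train_labels, dtype=int))
    scores = pipe.predict_proba(list(test_names))[:, 1]
    return evaluate_scores(test_labels, scores, threshold)
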