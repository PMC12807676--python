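"""The pairwise same-gene classifier: training table, random forest, CV.

The model answers one question: given the six-feature description of a
candidate transcript pair, what is the probability that the two
transcripts belong to the same gene?  Training labels come from a
reference annotation whose transcripts carry gene memberships; candidate
generation is identical at train and build time (negatives are cross-gene
pairs inside the 1 kb window — distant pairs never reach the classifier),
so the training distribution matches deployment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigError, ContractError, DegenerateTrainingError, InputError
from .features import DEFAULT_WINDOW, FEATURE_NAMES, PairFeatures, build_candidate_table
from .gff_io import TranscriptSet
from .ontology import TermEmbedding

TABLE_COLUMNS = ("id_a", "id_b", *FEATURE_NAMES, "label")


class SameGenePairClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest classifier over the six pair features.

    scikit-learn estimator: ``fit(X, y)`` on an (n_pairs, 6) matrix in the
    :data:`~ncgene.features.FEATURE_NAMES` order, ``predict_proba`` giving
    the same-gene probability used downstream as an edge weight.  Defaults:
    100 trees, unlimited depth, balanced class weights, fixed seed.

    Fitted attributes
    -----------------
    forest_ : the underlying ``RandomForestClassifier``
    feature_names_ : the feature-order contract serialized with the model
    data_fingerprint_ : SHA256 of the training matrix
    embedding_fingerprint_ : fingerprint of the term embedding the features
        were computed with (``None`` if not supplied), checked at build time
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_depth: int | None = None,
        class_weight: str | dict | None = "balanced",
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.class_weight = class_weight
        self.random_state = random_state

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise ContractError(
                f"feature matrix must have {len(FEATURE_NAMES)} columns in order {FEATURE_NAMES}, got shape {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ContractError("feature matrix contains non-finite values")
        return X

    def fit(self, X, y, embedding_fingerprint: str | None = None):
        X = self._validate(X)
        y = np.asarray(y, dtype=int)
        if X.shape[0] == 0:
            raise InputError("empty training table")
        if len(np.unique(y)) < 2:
            raise DegenerateTrainingError("all training labels identical; cannot fit a two-class model")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            class_weight=self.class_weight,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        self.feature_names_ = tuple(FEATURE_NAMES)
        self.n_features_in_ = X.shape[1]
        self.data_fingerprint_ = hashlib.sha256(np.ascontiguousarray(X).tobytes() + y.tobytes()).hexdigest()
        self.embedding_fingerprint_ = embedding_fingerprint
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(self._validate(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict(self._validate(X))

    def same_gene_probability(self, X) -> np.ndarray:
        """P(label = 1) per row; the downstream edge weight."""
        proba = self.predict_proba(X)
        return proba[:, list(self.classes_).index(1)]

    @property
    def gini_importances_(self) -> pd.Series:
        """Mean decrease in Gini impurity per feature, aggregated over trees."""
        check_is_fitted(self, "forest_")
        return pd.Series(self.forest_.feature_importances_, index=self.feature_names_)


@dataclass
class CVMetrics:
    """Per-fold and average accuracy, F1, AUC and average precision."""

    folds: pd.DataFrame  # columns: fold, accuracy, f1, auc, ap
    models: list[SameGenePairClassifier]

    @property
    def averages(self) -> pd.Series:
        return self.folds[["accuracy", "f1", "auc", "ap"]].mean()

    def to_tsv(self) -> str:
        rows = ["Fold\tAccuracy\tF1\tAUC\tAP"]
        for _, r in self.folds.iterrows():
            rows.append(f"{int(r['fold'])}\t{r['accuracy']:.6f}\t{r['f1']:.6f}\t{r['auc']:.6f}\t{r['ap']:.6f}")
        a = self.averages
        rows.append(f"Average\t{a['accuracy']:.6f}\t{a['f1']:.6f}\t{a['auc']:.6f}\t{a['ap']:.6f}")
        return "\n".join(rows) + "\n"


def build_training_set(
    ref: TranscriptSet, emb: TermEmbedding | None, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Labeled pair table from a reference annotation with gene memberships.

    Rows are exactly the candidate pairs; label 1 iff both transcripts carry
    the same reference gene id.  Raises if any transcript lacks a gene id or
    if only one class results.
    """
    missing = [t.transcript_id for t in ref.transcripts if t.gene_id is None]
    if missing:
        raise InputError(f"{len(missing)} reference transcripts lack a gene id (e.g. {missing[:3]})")
    gene_of = {t.transcript_id: t.gene_id for t in ref.transcripts}
    pairs = build_candidate_table(ref, emb, window)
    rows = []
    for p in pairs:
        label = int(gene_of[p.id_a] == gene_of[p.id_b])
        rows.append((p.id_a, p.id_b, *p.features.as_array(), label))
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    n_pos = int(table["label"].sum()) if len(table) else 0
    if len(table) == 0 or n_pos == 0 or n_pos == len(table):
        raise DegenerateTrainingError(
            f"labeled pair table is single-class ({n_pos} positives of {len(table)} rows)"
        )
    table.attrs["class_counts"] = {"positive": n_pos, "negative": len(table) - n_pos}
    return table


def _split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    return table[list(FEATURE_NAMES)].to_numpy(dtype=float), table["label"].to_numpy(dtype=int)


def train_classifier(
    table: pd.DataFrame,
    config: dict | None = None,
    seed: int = 0,
    embedding_fingerprint: str | None = None,
) -> SameGenePairClassifier:
    """Fit the forest on the full labeled table; deterministic for fixed seed."""
    X, y = _split_xy(table)
    clf = SameGenePairClassifier(random_state=seed, **(config or {}))
    return clf.fit(X, y, embedding_fingerprint=embedding_fingerprint)


def cross_validate(
    table: pd.DataFrame, k: int = 5, config: dict | None = None, seed: int = 0
) -> CVMetrics:
    """Stratified k-fold CV; fold assignment is deterministic by seed."""
    if k < 2:
        raise ConfigError(f"k-fold CV requires k >= 2, got {k}")
    X, y = _split_xy(table)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise InputError(f"stratified {k}-fold CV needs >= {k} rows per class, have {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    records, models = [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y), start=1):
        clf = SameGenePairClassifier(random_state=seed, **(config or {})).fit(X[train_idx], y[train_idx])
        prob = clf.same_gene_probability(X[test_idx])
        pred = (prob >= 0.5).astype(int)
        records.append(
            {
                "fold": fold,
                "accuracy": accuracy_score(y[test_idx], pred),
                "f1": f1_score(y[test_idx], pred),
                "auc": roc_auc_score(y[test_idx], prob),
                "ap": average_precision_score(y[test_idx], prob),
            }
        )
        models.append(clf)
    return CVMetrics(folds=pd.DataFrame(records), models=models)


def predict_pair(model: SameGenePairClassifier, f: PairFeatures) -> float:
    """Same-gene probability for one feature vector."""
    return float(model.same_gene_probability(f.as_array()[None, :])[0])


def feature_importances(
    model: SameGenePairClassifier, cv_models: list[SameGenePairClassifier] | None = None
) -> pd.DataFrame:
    """Mean Gini importance per feature across folds, with across-fold std.

    With no CV models, the single model's importances are reported with zero
    dispersion.  Means sum to 1 (each forest's importances are normalized).
    """
    models = list(cv_models) if cv_models else [model]
    mat = np.vstack([m.gini_importances_.to_numpy() for m in models])
    return pd.DataFrame(
        {"importance": mat.mean(axis=0), "std": mat.std(axis=0)}, index=list(FEATURE_NAMES)
    )


def importances_to_tsv(imp: pd.DataFrame) -> str:
    lines = ["feature\timportance\tstd"]
    for name, row in imp.iterrows():
        lines.append(f"{name}\t{row['importance']:.6f}\t{row['std']:.6f}")
    return "\n".join(lines) + "\n"


# -- model archive -----------------------------------------------------------


def save_model(model: SameGenePairClassifier, path: str | Path) -> None:
    """Single-file archive: the fitted estimator plus a JSON header with the
    feature-order contract, seed and data/embedding fingerprints."""
    check_is_fitted(model, "forest_")
    header = {
        "format": "ncgene-model/1",
        "feature_order": list(model.feature_names_),
        "random_state": model.random_state,
        "data_fingerprint": model.data_fingerprint_,
        "embedding_fingerprint": model.embedding_fingerprint_,
    }
    joblib.dump({"header": header, "model": model}, path)


def load_model(path: str | Path) -> SameGenePairClassifier:
    payload = joblib.load(path)
    header = payload.get("header", {})
    if header.get("format") != "ncgene-model/1":
        raise ContractError(f"{path}: not an ncgene model archive")
    model = payload["model"]
    if list(model.feature_names_) != header["feature_order"]:
        raise ContractError("model archive header disagrees with stored feature order")
    return model


def model_header(path: str | Path) -> dict:
    return joblib.load(path)["header"]
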