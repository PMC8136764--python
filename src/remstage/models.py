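"""Classifiers with the study's hyper-parameters and rebalancing procedures.

* K-NN: K = 10, Euclidean metric, inverse-distance-weighted vote.
* Random forest: 30 trees, per-tree node cap of 0.2 x NF split nodes
  (NF = number of features after selection), random feature subsets per node.
* RUSBoost: 30 boosting rounds; every round randomly undersamples each
  class to the size of the least-represented class before fitting the weak
  tree, with SAMME-style weight updates.
* Decision tree (unrestricted depth) and RBF-kernel SVM for the binary
  REM-vs-NREM task.

A separate undersampling helper reduces a dominant class (typically N2) to
the mean count of the other sleep stages prior to training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigError, DataError
from .types import STAGES

MODEL_KINDS = ("rf", "knn", "rusboost", "dt", "svm")

#: Stage order used for deterministic tie-breaks (lowest index wins).
STAGE_ORDER = list(STAGES)


@dataclass
class ModelSpec:
    """Classifier kind, seed and optional hyper-parameter overrides."""

    kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS and self.kind != "custom":
            raise ConfigError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")


def node_cap(n_features: int) -> int:
    """Per-tree cap on split nodes: max(2, floor(0.2 * NF))."""
    if n_features < 1:
        raise ConfigError("need at least one feature")
    return max(2, int(np.floor(0.2 * n_features)))


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """Boosted trees with per-round random undersampling (RUSBoost).

    Each of ``n_estimators`` rounds draws, uniformly at random without
    replacement, ``n_min`` examples from every class (``n_min`` = size of
    the smallest class), fits a weak tree on the balanced sample using the
    current boosting weights, and updates the weights with the multi-class
    (SAMME) rule.  ``round_class_counts_`` records the per-round class
    counts actually used.
    """

    def __init__(self, n_estimators: int = 30, max_leaf_nodes: int | None = None,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_leaf_nodes = max_leaf_nodes
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = self.classes_.size
        if k < 2:
            raise DataError("RUSBoost requires at least two classes")
        rng = np.random.default_rng(self.random_state)
        n = y.size
        n_min = int(np.bincount(y_idx).min())

        w = np.full(n, 1.0 / n)
        self.estimators_, self.alphas_ = [], []
        self.round_class_counts_: list[dict] = []
        for _ in range(self.n_estimators):
            sample = np.concatenate([
                rng.choice(np.flatnonzero(y_idx == c), size=n_min, replace=False)
                for c in range(k)
            ])
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_leaf_nodes,
                random_state=int(rng.integers(2 ** 31 - 1)),
            )
            sw = w[sample]
            tree.fit(X[sample], y_idx[sample], sample_weight=sw / sw.sum())
            self.round_class_counts_.append(
                {self.classes_[c]: int(np.sum(y_idx[sample] == c)) for c in range(k)}
            )
            pred = tree.predict(X)
            miss = pred != y_idx
            err = float(w[miss].sum() / w.sum())
            if err <= 0:
                self.estimators_.append(tree)
                self.alphas_.append(10.0)  # perfect weak learner dominates
                break
            if err >= 1 - 1.0 / k:
                continue  # weaker than chance on current weights; discard round
            alpha = np.log((1 - err) / err) + np.log(k - 1)
            w *= np.exp(alpha * miss)
            w /= w.sum()
            self.estimators_.append(tree)
            self.alphas_.append(float(alpha))
        if not self.estimators_:
            raise DataError("RUSBoost found no usable weak learner")
        return self

    def decision_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        scores = np.zeros((X.shape[0], self.classes_.size))
        for tree, alpha in zip(self.estimators_, self.alphas_):
            pred = tree.predict(X)
            scores[np.arange(X.shape[0]), pred] += alpha
        return scores

    def predict(self, X):
        # argmax breaks ties toward the lowest class index
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]


def make_estimator(spec: ModelSpec, n_features: int):
    """Instantiate the classifier for ``spec`` given the selected NF."""
    p = spec.params
    if spec.kind == "custom":
        return clone(p["estimator"])
    if spec.kind == "knn":
        return KNeighborsClassifier(
            n_neighbors=p.get("n_neighbors", 10), weights="distance",
            metric="euclidean",
        )
    cap = node_cap(n_features)
    if spec.kind == "rf":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 30),
            max_leaf_nodes=cap + 1,  # `cap` split nodes
            random_state=spec.seed,
        )
    if spec.kind == "rusboost":
        return RUSBoostClassifier(
            n_estimators=p.get("n_estimators", 30),
            max_leaf_nodes=cap + 1,
            random_state=spec.seed,
        )
    if spec.kind == "dt":
        return DecisionTreeClassifier(random_state=spec.seed)
    if spec.kind == "svm":
        return SVC(kernel=p.get("kernel", "rbf"), random_state=spec.seed)
    raise ConfigError(f"unknown model kind {spec.kind!r}")


def train(spec: ModelSpec, features: pd.DataFrame, labels) -> object:
    """Fit the classifier; the feature-name manifest is attached for
    prediction-time validation."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise DataError("training set must contain at least two classes")
    if features.shape[1] < 1:
        raise DataError("no features left after selection")
    est = make_estimator(spec, features.shape[1])
    est.fit(np.asarray(features, dtype=float), y)
    est.feature_manifest_ = list(features.columns)
    return est


def predict(model, features: pd.DataFrame) -> np.ndarray:
    """Predict one label per row after validating the feature manifest."""
    if len(features) == 0:
        raise DataError("empty feature matrix")
    manifest = getattr(model, "feature_manifest_", None)
    if manifest is not None:
        missing = [c for c in manifest if c not in features.columns]
        extra = [c for c in features.columns if c not in manifest]
        if missing or extra:
            raise DataError(
                f"feature manifest mismatch: missing {missing}, unexpected {extra}"
            )
        features = features[manifest]
    return np.asarray(model.predict(np.asarray(features, dtype=float)))


# ---------------------------------------------------------------------------
# class rebalancing and the binary task


def undersample_to_mean(
    features: pd.DataFrame,
    labels,
    majority_class: str = "N2",
    classes_for_mean: tuple[str, ...] = ("REM", "N1", "N3"),
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Randomly subsample the majority class to the rounded mean count of
    the named other classes; all other rows pass through untouched."""
    y = np.asarray(labels)
    if majority_class not in y:
        raise DataError(f"majority class {majority_class!r} absent from labels")
    target = int(round(float(np.mean([np.sum(y == c) for c in classes_for_mean]))))
    maj_idx = np.flatnonzero(y == majority_class)
    if maj_idx.size <= target:
        return features, y
    rng = np.random.default_rng(seed)
    keep_maj = rng.choice(maj_idx, size=target, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(y != majority_class), keep_maj]))
    return features.iloc[keep].reset_index(drop=True), y[keep]


def to_binary(features: pd.DataFrame, labels) -> tuple[pd.DataFrame, np.ndarray]:
    """REM-vs-NREM relabelling: AWA rows dropped, N1/N2/N3 -> NREM."""
    y = np.asarray(labels)
    keep = np.flatnonzero(y != "AWA")
    if keep.size == 0:
        raise DataError("no rows left after discarding AWA")
    mapped = np.where(y[keep] == "REM", "REM", "NREM")
    return features.iloc[keep].reset_index(drop=True), mapped


# ---------------------------------------------------------------------------
# persistence

_FORMAT_VERSION = 1


def save_model(model, path: str | Path, *, scaler=None, kept_features=None,
               bands=None, spec: ModelSpec | None = None, meta: dict | None = None
               ) -> Path:
    """Persist a fitted model with its feature manifest and band definitions."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "model": model,
        "scaler": scaler,
        "kept_features": kept_features or getattr(model, "feature_manifest_", None),
        "bands": bands,
        "spec": spec,
        "meta": meta or {},
    }
    joblib.dump(payload, path)
    return Path(path)


def load_model(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise DataError(f"model file not found: {path}")
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format_version") != _FORMAT_VERSION:
        raise DataError(f"{path} is not a recognized model file")
    return payload
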