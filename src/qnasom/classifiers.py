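"""Atom-level SOM classifiers behind a single fit/score contract.

Four configurations are provided, with defaults matching the study
protocol:

* ``naive_bayes`` — Gaussian naive Bayes on the two continuous features.
* ``random_forest`` — 100 trees, each grown on a bootstrap sample of 70%
  of the training rows.
* ``rbf_network`` — a bespoke radial-basis-function network: k-means with
  two clusters pre-trains the Gaussian basis centers, each basis width is
  the RMS radius of its cluster, activations below 1e-8 are clamped to
  zero, and a logistic-regression output layer maps activations to a
  class probability.
* ``mlp`` — multilayer perceptron with two hidden layers of 10 tanh units,
  early-stopped on an internal 20% validation carve-out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier

from .dataset import SomDataset

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "FittedModel",
    "RbfNetwork",
    "fit",
    "predict_proba",
    "save_model",
    "load_model",
]

CLASSIFIER_KINDS = ("naive_bayes", "random_forest", "rbf_network", "mlp")

_KIND_ALIASES = {
    "nb": "naive_bayes",
    "rf": "random_forest",
    "rbf": "rbf_network",
    "mlp": "mlp",
}

_PERSIST_FORMAT = 1


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind plus hyperparameter overrides and RNG seed."""

    kind: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        kind = _KIND_ALIASES.get(self.kind, self.kind)
        object.__setattr__(self, "kind", kind)
        if kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; valid: {CLASSIFIER_KINDS}")


class RbfNetwork:
    """RBF network: k-means basis placement, Gaussian activations with an
    activation floor, logistic output.

    Parameters
    ----------
    n_clusters : number of Gaussian basis functions (default 2).
    activation_floor : activations below this are clamped to 0 (default 1e-8).
    """

    def __init__(
        self,
        n_clusters: int = 2,
        activation_floor: float = 1e-8,
        random_state: int = 0,
    ) -> None:
        self.n_clusters = n_clusters
        self.activation_floor = activation_floor
        self.random_state = random_state

    def _activations(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        phi = np.exp(-d2 / (2.0 * self.widths_**2))
        phi[phi < self.activation_floor] = 0.0
        return phi

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RbfNetwork":
        km = KMeans(
            n_clusters=self.n_clusters, n_init=10, random_state=self.random_state
        ).fit(X)
        self.cluster_centers_ = km.cluster_centers_
        widths = np.empty(self.n_clusters)
        for j in range(self.n_clusters):
            members = X[km.labels_ == j]
            if len(members) == 0:
                widths[j] = 1.0
                continue
            r2 = ((members - self.cluster_centers_[j]) ** 2).sum(axis=1)
            widths[j] = np.sqrt(r2.mean())
        # degenerate cluster (single point / duplicates): fall back to the
        # global scale so the Gaussian stays well-defined
        fallback = np.sqrt(X.var(axis=0).sum()) or 1.0
        self.widths_ = np.where(widths > 0, widths, fallback)
        self._out = LogisticRegression(max_iter=1000, random_state=self.random_state)
        self._out.fit(self._activations(X), y)
        self.classes_ = self._out.classes_
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._out.predict_proba(self._activations(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._out.predict(self._activations(X))


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.rng_seed
    if spec.kind == "naive_bayes":
        return GaussianNB(**hp)
    if spec.kind == "random_forest":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("max_samples", 0.7)
        return RandomForestClassifier(bootstrap=True, random_state=seed, **hp)
    if spec.kind == "rbf_network":
        hp.setdefault("n_clusters", 2)
        hp.setdefault("activation_floor", 1e-8)
        return RbfNetwork(random_state=seed, **hp)
    if spec.kind == "mlp":
        hp.setdefault("hidden_layer_sizes", (10, 10))
        hp.setdefault("activation", "tanh")
        hp.setdefault("early_stopping", True)
        hp.setdefault("validation_fraction", 0.2)
        hp.setdefault("max_iter", 500)
        return MLPClassifier(random_state=seed, **hp)
    raise AssertionError(spec.kind)


@dataclass
class FittedModel:
    """A trained classifier plus its training metadata."""

    spec: ClassifierSpec
    estimator: Any
    n_rows: int
    class_counts: dict[int, int]
    normalizer_id: str = ""


def fit(spec: ClassifierSpec, train: SomDataset, normalizer_id: str = "") -> FittedModel:
    """Train the classifier described by ``spec`` on a (normalized,
    optionally SMOTE-balanced) training dataset.

    Deterministic given the spec's seed.  Raises on a single-class
    training set.
    """
    X, y = train.features, train.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set has a single class; cannot fit a classifier")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values in training set")
    estimator = _build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        estimator.fit(X, y)
    return FittedModel(
        spec=spec,
        estimator=estimator,
        n_rows=len(train),
        class_counts={int(c): int(n) for c, n in zip(classes, counts)},
        normalizer_id=normalizer_id,
    )


def predict_proba(model: FittedModel, rows: np.ndarray | SomDataset) -> np.ndarray:
    """Per-row probability of label 1 (SOM), in [0, 1]."""
    X = rows.features if isinstance(rows, SomDataset) else np.atleast_2d(rows)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    proba = model.estimator.predict_proba(X)
    pos_col = int(np.where(model.estimator.classes_ == 1)[0][0])
    return proba[:, pos_col]


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist a fitted model to a single self-describing archive."""
    joblib.dump({"format": _PERSIST_FORMAT, "model": model}, path)


def load_model(path: str | Path) -> FittedModel:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != _PERSIST_FORMAT:
        raise ValueError(f"{path}: not a recognized model archive")
    return payload["model"]
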