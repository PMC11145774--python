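"""Classifier configuration and small verification utilities.

Seven classifiers are supported — decision tree (DT), random forest (RF),
k-nearest neighbours (KNN), categorical naive Bayes (CNB), linear-kernel SVM,
bagged multilayer perceptrons, and a stacking ensemble (DT+RF+CNB+KNN bases
with an RF meta-learner).  Training itself is delegated to scikit-learn; this
module pins the hyperparameters, wires one seed through every stochastic
learner, and provides audited stand-alone implementations of the Gini
impurity and Minkowski distance used by the tree and neighbour models.

Defaults: RF 100 trees, unlimited depth, min-samples-split 2, min-samples-leaf
1, Gini criterion; KNN 3 neighbours on the Minkowski metric (p=2); CNB with
Laplace smoothing alpha=1 and fitted priors; SVM linear kernel, degree 3,
gamma "scale"; bagging of 10 MLPs with one hidden layer of 100 units capped
at 1000 iterations; stacking meta-features from 5-fold cross-validated base
predictions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (
    BaggingClassifier,
    RandomForestClassifier,
    StackingClassifier,
)
from sklearn.naive_bayes import CategoricalNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MODEL_NAMES = ("dt", "rf", "knn", "cnb", "svm", "bagging", "stacking")


@dataclass(frozen=True)
class ModelConfig:
    """A named classifier, its hyperparameter overrides and a seed."""

    model_name: str
    seed: int = 0
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_NAMES:
            raise ValueError(
                f"unknown model {self.model_name!r}; expected one of {MODEL_NAMES}"
            )


class TieBreakKNN(KNeighborsClassifier):
    """KNN whose vote ties break toward the closest class, then the lowest label.

    With 3 neighbours and six classes a 1-1-1 vote is possible; the tied class
    with the smallest summed neighbour distance wins, remaining ties go to the
    lowest ordinal code.
    """

    def predict(self, X):
        dist, idx = self.kneighbors(X)
        y_train = self._y  # integer-encoded training labels
        out = np.empty(len(idx), dtype=int)
        for row, (d_row, i_row) in enumerate(zip(dist, idx)):
            votes = y_train[i_row]
            labels, counts = np.unique(votes, return_counts=True)
            tied = labels[counts == counts.max()]
            if len(tied) == 1:
                out[row] = tied[0]
            else:
                sums = [d_row[votes == lab].sum() for lab in tied]
                out[row] = int(tied[int(np.argmin(sums))])  # argmin is stable
        return self.classes_[out]


def _rf(seed: int, **over) -> RandomForestClassifier:
    params = dict(
        n_estimators=100,
        criterion="gini",
        min_samples_split=2,
        max_depth=None,
        min_samples_leaf=1,
        random_state=seed,
    )
    params.update(over)
    return RandomForestClassifier(**params)


def build_model(config: ModelConfig) -> BaseEstimator:
    """Instantiate the configured (unfitted) scikit-learn estimator."""
    name, seed = config.model_name, config.seed
    over = dict(config.hyperparameters)
    if name == "dt":
        params = dict(criterion="gini", random_state=seed)
        params.update(over)
        return DecisionTreeClassifier(**params)
    if name == "rf":
        return _rf(seed, **over)
    if name == "knn":
        params = dict(n_neighbors=3, metric="minkowski", p=2)
        params.update(over)
        return TieBreakKNN(**params)
    if name == "cnb":
        params = dict(alpha=1.0, force_alpha=True, fit_prior=True, min_categories=6)
        params.update(over)
        return CategoricalNB(**params)
    if name == "svm":
        params = dict(kernel="linear", degree=3, gamma="scale", random_state=seed)
        params.update(over)
        return SVC(**params)
    if name == "bagging":
        mlp = MLPClassifier(
            hidden_layer_sizes=(over.pop("hidden_layer_sizes", 100),),
            max_iter=over.pop("max_iter", 1000),
            random_state=seed,
        )
        params = dict(estimator=mlp, n_estimators=10, random_state=seed)
        params.update(over)
        return BaggingClassifier(**params)
    if name == "stacking":
        cnb_over = over.pop("cnb", {})
        bases = [
            ("dt", build_model(ModelConfig("dt", seed))),
            ("rf", build_model(ModelConfig("rf", seed))),
            ("cnb", build_model(ModelConfig("cnb", seed, cnb_over))),
            ("knn", build_model(ModelConfig("knn", seed))),
        ]
        params = dict(estimators=bases, final_estimator=_rf(seed), cv=5)
        params.update(over)
        return StackingClassifier(**params)
    raise ValueError(f"unknown model {name!r}")  # pragma: no cover


@dataclass
class TrainedModel:
    """A fitted estimator bundled with its config for provenance."""

    config: ModelConfig
    estimator: BaseEstimator

    @property
    def classes(self) -> np.ndarray:
        return self.estimator.classes_


def build_and_train(config: ModelConfig, X, y) -> TrainedModel:
    """Build the configured model and fit it; requires at least two classes."""
    X = np.asarray(X)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("cannot train on an empty feature table")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain fewer than two classes")
    est = clone(build_model(config))
    est.fit(X, y)
    return TrainedModel(config=config, estimator=est)


def predict(model: TrainedModel, X) -> np.ndarray:
    """Predict one label per row (labels are drawn from the training classes)."""
    X = np.asarray(X)
    if len(X) == 0:
        return np.array([], dtype=model.classes.dtype)
    n_expected = model.estimator.n_features_in_
    if X.shape[1] != n_expected:
        raise ValueError(
            f"feature dimensionality {X.shape[1]} != training dimensionality "
            f"{n_expected}"
        )
    return model.estimator.predict(X)


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump({"config": model.config, "estimator": model.estimator}, path)


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    return TrainedModel(config=blob["config"], estimator=blob["estimator"])


def minkowski_distance(x: Sequence[float], y: Sequence[float], p: float = 2) -> float:
    """Minkowski distance (sum |x_i - y_i|^p)^(1/p); a metric for p >= 1."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"dimension mismatch: {xa.shape} vs {ya.shape}")
    if p < 1:
        raise ValueError("p must be >= 1")
    return float(np.sum(np.abs(xa - ya) ** p) ** (1.0 / p))


def gini_impurity(class_proportions: Sequence[float]) -> float:
    """Gini impurity 1 - sum P_k^2 of a node's class distribution."""
    p = np.asarray(class_proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()}, not 1")
    return float(1.0 - np.sum(p**2))
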