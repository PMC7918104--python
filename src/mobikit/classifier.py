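"""Faller/non-faller classification with a small feed-forward network.

The classifier is a fully connected perceptron with two tanh hidden
layers of equal width and a single sigmoid output, trained by full-batch
gradient descent on the cross-entropy loss for a fixed number of epochs,
optionally with an L2 weight penalty.  It is deliberately tiny — the
feature sets have at most 84 inputs and cohorts tens of subjects — and
fully deterministic under a seed.

:class:`TanhMLPClassifier` follows the scikit-learn estimator protocol
(``fit`` / ``predict`` / ``predict_proba``, ``get_params``, fitted
attributes with trailing underscores) and embeds per-fit feature
standardisation, so leave-one-out evaluation cannot leak the held-out
subject into the scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import InputError, SpecError
from .metrics import MetricsReport
from .types import FeatureVector

#: Hyperparameter grid evaluated by grid_evaluate, in report row order.
GRID_NEURONS = (5, 7, 10)
GRID_EPOCHS = (2, 4, 20)
GRID_REGULARISATION = (False, True)


@dataclass
class NetworkSpec:
    """One network configuration of the evaluation grid."""

    neurons: int = 7             # width of each of the two hidden layers
    epochs: int = 20             # full-batch gradient steps
    l2: bool = False             # L2 weight penalty on/off
    learning_rate: float = 1.0
    l2_coef: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neurons <= 0:
            raise SpecError("neurons must be > 0")
        if self.epochs <= 0:
            raise SpecError("epochs must be > 0")


@dataclass
class Dataset:
    """Feature matrix with string labels for one input set."""

    X: np.ndarray
    y: np.ndarray
    feature_names: List[str]
    subject_ids: List[str]
    set_name: str = ""
    positive_label: str = "faller"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise InputError("feature matrix and labels disagree")
        if not np.all(np.isfinite(self.X)):
            raise InputError("features contain missing values")

    @classmethod
    def from_features(cls, features: Sequence[FeatureVector], labels: Dict[str, str],
                      set_name: str = "", positive_label: str = "faller") -> "Dataset":
        names = list(features[0].values)
        X = np.stack([fv.as_array(names) for fv in features])
        subject_ids = [fv.subject_id for fv in features]
        y = np.array([labels[s] for s in subject_ids])
        return cls(X, y, names, subject_ids, set_name or features[0].set_name,
                   positive_label)

    def __len__(self) -> int:
        return len(self.y)


class TanhMLPClassifier(BaseEstimator, ClassifierMixin):
    """Two-hidden-layer tanh perceptron with a sigmoid output.

    Parameters mirror :class:`NetworkSpec`; ``hidden_units`` is the width
    of both hidden layers.  Features are z-scored inside ``fit`` using
    the training data only.
    """

    def __init__(self, hidden_units: int = 7, epochs: int = 20, l2: bool = False,
                 learning_rate: float = 1.0, l2_coef: float = 0.01,
                 random_state: int = 0):
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.l2 = l2
        self.learning_rate = learning_rate
        self.l2_coef = l2_coef
        self.random_state = random_state

    # -- scikit-learn protocol -------------------------------------------------

    def fit(self, X, y) -> "TanhMLPClassifier":
        if self.hidden_units <= 0:
            raise SpecError("hidden_units must be > 0")
        if self.epochs <= 0:
            raise SpecError("epochs must be > 0")
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise InputError("training data contain a single class")
        if len(self.classes_) > 2:
            raise InputError("binary classifier: more than two classes given")
        t = (y == self.classes_[1]).astype(float)

        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        self.scale_ = np.where(scale > 1e-12, scale, 1.0)
        Xs = (X - self.mean_) / self.scale_

        rng = np.random.default_rng(self.random_state)
        d, h = X.shape[1], self.hidden_units
        # modest gaussian init scaled by fan-in
        w1 = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, h))
        b1 = np.zeros(h)
        w2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=(h, h))
        b2 = np.zeros(h)
        w3 = rng.normal(0.0, 1.0 / np.sqrt(h), size=(h, 1))
        b3 = np.zeros(1)
        n = len(Xs)
        lr = self.learning_rate
        lam = self.l2_coef if self.l2 else 0.0
        for _ in range(self.epochs):
            a1 = np.tanh(Xs @ w1 + b1)
            a2 = np.tanh(a1 @ w2 + b2)
            p = 1.0 / (1.0 + np.exp(-(a2 @ w3 + b3)))
            # cross-entropy gradient at the sigmoid output
            delta3 = (p - t[:, None]) / n
            delta2 = (delta3 @ w3.T) * (1.0 - a2 ** 2)
            delta1 = (delta2 @ w2.T) * (1.0 - a1 ** 2)
            w3 -= lr * (a2.T @ delta3 + lam * w3)
            b3 -= lr * delta3.sum(axis=0)
            w2 -= lr * (a1.T @ delta2 + lam * w2)
            b2 -= lr * delta2.sum(axis=0)
            w1 -= lr * (Xs.T @ delta1 + lam * w1)
            b1 -= lr * delta1.sum(axis=0)
        self.weights_ = [(w1, b1), (w2, b2), (w3, b3)]
        self.n_features_in_ = d
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise InputError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}")
        Xs = (X - self.mean_) / self.scale_
        (w1, b1), (w2, b2), (w3, b3) = self.weights_
        a = np.tanh(np.tanh(Xs @ w1 + b1) @ w2 + b2)
        return (a @ w3 + b3).ravel()

    def predict_proba(self, X) -> np.ndarray:
        """Column 1 is the probability of classes_[1]."""
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return np.where(p >= 0.5, self.classes_[1], self.classes_[0])


# -- module-level operations ---------------------------------------------------


def _estimator(spec: NetworkSpec) -> TanhMLPClassifier:
    return TanhMLPClassifier(hidden_units=spec.neurons, epochs=spec.epochs,
                             l2=spec.l2, learning_rate=spec.learning_rate,
                             l2_coef=spec.l2_coef, random_state=spec.seed)


def train(dataset: Dataset, spec: NetworkSpec) -> TanhMLPClassifier:
    """Fit one network on the full dataset."""
    return _estimator(spec).fit(dataset.X, dataset.y)


def predict(model: TanhMLPClassifier, X) -> Tuple[np.ndarray, np.ndarray]:
    """(labels, faller-probability scores) for new cases."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return model.predict(X), model.predict_proba(X)[:, 1]


def loocv(dataset: Dataset, spec: NetworkSpec) -> MetricsReport:
    """Leave-one-out cross-validation: n folds, one subject held out each.

    Standardisation and training use only the n-1 retained subjects;
    confusion counts accumulate over the held-out predictions.  Folds
    whose training split collapses to one class are skipped with a
    warning and reported in the result.
    """
    n = len(dataset)
    if n < 3:
        raise InputError("leave-one-out needs at least 3 subjects")
    pos = dataset.positive_label
    counts = {"tp": 0.0, "fn": 0.0, "tn": 0.0, "fp": 0.0}
    skipped = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = dataset.y[mask]
        if len(np.unique(y_train)) < 2:
            warnings.warn(f"fold {i}: single-class training split, skipped")
            skipped += 1
            continue
        fold_spec = NetworkSpec(**{**spec.__dict__, "seed": spec.seed + i})
        model = _estimator(fold_spec).fit(dataset.X[mask], y_train)
        pred = model.predict(dataset.X[i:i + 1])[0]
        truth = dataset.y[i]
        if truth == pos:
            counts["tp" if pred == pos else "fn"] += 1
        else:
            counts["tn" if pred != pos else "fp"] += 1
    return MetricsReport.from_counts(counts, n_skipped_folds=skipped)


def grid_evaluate(dataset: Dataset, base_seed: int = 0) -> List[dict]:
    """LOOCV over all 18 grid configurations, in report row order.

    Returns rows with the hyperparameters and the resulting rates,
    suitable for :func:`mobikit.metrics.marginal_means`.
    """
    rows = []
    for neurons in GRID_NEURONS:
        for epochs in GRID_EPOCHS:
            for reg in GRID_REGULARISATION:
                spec = NetworkSpec(neurons=neurons, epochs=epochs, l2=reg,
                                   seed=base_seed)
                rep = loocv(dataset, spec)
                rows.append({
                    "neurons": neurons, "epochs": epochs, "regularisation": reg,
                    "tpr": rep.tpr, "tnr": rep.tnr, "acc": rep.acc,
                    "mcc": rep.mcc, "j": rep.j,
                    "n_skipped_folds": rep.n_skipped_folds,
                })
    return rows
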