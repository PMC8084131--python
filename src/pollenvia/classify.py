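"""Linear-SVM viability classifier.

The classifier separates viable (stained) from non-viable (transparent)
grains in the 19-feature space.  Training follows a fixed protocol: a seeded
stratified 70/30 train/validation split, feature standardization fitted on
the training portion only, and a soft-margin linear SVM capped at 500 solver
iterations.  Validation accuracy on the held-out 30% is stored with the
model.

:class:`ViabilityClassifier` is a scikit-learn-compatible estimator
(``fit``/``predict``/``decision_function``, ``get_params``/``set_params``),
so it composes with sklearn pipelines and model selection.  The module-level
``train_svm``/``predict``/``save_model``/``load_model`` functions are thin
wrappers for script use.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import LinearSVC

from .features import FeatureScaler, GrainFeatures, N_FEATURES, _as_matrix

__all__ = [
    "ViabilityClassifier",
    "LabeledFeatureSet",
    "train_svm",
    "predict",
    "save_model",
    "load_model",
]

VIABLE = "viable"
NONVIABLE = "nonviable"
_MODEL_FORMAT_VERSION = 1


class LabeledFeatureSet:
    """Parallel lists of grain features and {viable, nonviable} labels."""

    def __init__(self, features, labels):
        self.X = _as_matrix(features)
        labels = list(labels)
        if len(labels) != self.X.shape[0]:
            raise ValueError("features and labels must have equal length")
        bad = set(labels) - {VIABLE, NONVIABLE}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        self.labels = np.asarray(labels, dtype=object)

    def __len__(self):
        return self.X.shape[0]


def _stratified_split(y: np.ndarray, train_fraction: float, seed: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-class 70/30 split.

    Classes are processed in order of first occurrence in ``y``, so the
    selected row indices depend only on the class *partition*, not on which
    class is called viable — relabeling the classes keeps the split and
    flips only the signs.
    """
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    _, first = np.unique(y, return_index=True)
    for c in y[np.sort(first)]:
        idx = np.flatnonzero(y == c)
        perm = idx[rng.permutation(idx.size)]
        n_tr = int(np.floor(train_fraction * idx.size))
        n_tr = min(max(n_tr, 1), idx.size - 1)  # keep both sides non-empty
        train_idx.append(perm[:n_tr])
        val_idx.append(perm[n_tr:])
    return np.sort(np.concatenate(train_idx)), \
        np.sort(np.concatenate(val_idx))


class ViabilityClassifier(BaseEstimator, ClassifierMixin):
    """Soft-margin linear SVM with the fixed 70/30 training protocol.

    Parameters
    ----------
    C : float
        Soft-margin regularization strength (default 1.0).
    max_iterations : int
        Solver iteration cap (default 500).
    train_fraction : float
        Share of the data used for training; the remainder is the held-out
        validation set (default 0.70, stratified per class).
    seed : int
        Seed for the split and the solver; fixes the model bitwise.

    Fitted attributes
    -----------------
    coef_ : (19,) weight vector in scaled-feature space.
    intercept_ : bias term.
    scaler_ : the :class:`FeatureScaler` fitted on the training portion.
    validation_accuracy_ : accuracy on the held-out 30%.
    n_train_, n_validation_ : split sizes (sum to n).
    classes_ : array(['nonviable', 'viable']).

    The decision rule is margin = w . scaled(x) + b; margin > 0 predicts
    viable, margin <= 0 predicts non-viable (ties go to non-viable).
    """

    def __init__(self, C: float = 1.0, max_iterations: int = 500,
                 train_fraction: float = 0.70, seed: int = 0,
                 tol: float = 1e-5):
        self.C = C
        self.max_iterations = max_iterations
        self.train_fraction = train_fraction
        self.seed = seed
        self.tol = tol

    # -- sklearn API --------------------------------------------------

    def fit(self, X, y):
        X = _as_matrix(X) if not isinstance(X, np.ndarray) else np.asarray(
            X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"X must be (n, {N_FEATURES})")
        y = np.asarray(list(y), dtype=object)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        classes = set(y)
        if classes - {VIABLE, NONVIABLE}:
            raise ValueError(f"unknown labels: {sorted(classes - {VIABLE, NONVIABLE})}")
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        n = X.shape[0]
        if n < 10:
            raise ValueError("need at least 10 labeled grains to train")

        # class encoding fixed: viable = +1, nonviable = -1
        y_num = np.where(y == VIABLE, 1, -1)
        tr_idx, va_idx = _stratified_split(y_num, self.train_fraction,
                                           self.seed)
        X_tr, X_va = X[tr_idx], X[va_idx]
        y_tr, y_va = y_num[tr_idx], y_num[va_idx]

        scaler = FeatureScaler().fit(X_tr)
        Z_tr = scaler.transform(X_tr)
        svc = LinearSVC(C=self.C, max_iter=self.max_iterations,
                        random_state=self.seed, tol=self.tol)
        svc.fit(Z_tr, y_tr)
        # orient weights so that +1 (viable) lies on the positive side
        sign = 1.0 if svc.classes_[-1] == 1 else -1.0
        self.coef_ = sign * svc.coef_.ravel().astype(np.float64)
        self.intercept_ = float(sign * svc.intercept_[0])
        self.scaler_ = scaler
        self.classes_ = np.array([NONVIABLE, VIABLE], dtype=object)
        self.n_train_ = int(X_tr.shape[0])
        self.n_validation_ = int(X_va.shape[0])
        margins_va = scaler.transform(X_va) @ self.coef_ + self.intercept_
        pred_va = np.where(margins_va > 0, 1, -1)
        self.validation_accuracy_ = float(np.mean(pred_va == y_va))
        self.training_meta_ = {
            "seed": int(self.seed),
            "max_iterations": int(self.max_iterations),
            "train_fraction": float(self.train_fraction),
            "C": float(self.C),
            "n_train": self.n_train_,
            "n_validation": self.n_validation_,
            "validation_accuracy": self.validation_accuracy_,
        }
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signed margins w . scaled(x) + b."""
        self._check_fitted()
        X = _as_matrix(X) if not isinstance(X, np.ndarray) else np.asarray(
            X, dtype=np.float64)
        one = X.ndim == 1
        if one:
            X = X[None, :]
        if X.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
        m = self.scaler_.transform(X) @ self.coef_ + self.intercept_
        return m[0] if one else m

    def predict(self, X) -> np.ndarray:
        m = np.atleast_1d(self.decision_function(X))
        return np.where(m > 0, VIABLE, NONVIABLE).astype(object)

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("classifier is not fitted")

    # -- persistence ---------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "format_version": _MODEL_FORMAT_VERSION,
            "weights": self.coef_.tolist(),
            "bias": self.intercept_,
            "scaler": {"mean": self.scaler_.mean.tolist(),
                       "sd": self.scaler_.sd.tolist()},
            "training_meta": self.training_meta_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ViabilityClassifier":
        if d.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: "
                             f"{d.get('format_version')!r}")
        meta = d["training_meta"]
        model = cls(C=meta.get("C", 1.0), max_iterations=meta["max_iterations"],
                    train_fraction=meta["train_fraction"], seed=meta["seed"])
        model.coef_ = np.asarray(d["weights"], dtype=np.float64)
        if model.coef_.shape != (N_FEATURES,):
            raise ValueError("model weight vector must have 19 entries")
        model.intercept_ = float(d["bias"])
        model.scaler_ = FeatureScaler(
            mean=np.asarray(d["scaler"]["mean"], dtype=np.float64),
            sd=np.asarray(d["scaler"]["sd"], dtype=np.float64))
        model.classes_ = np.array([NONVIABLE, VIABLE], dtype=object)
        model.n_train_ = int(meta["n_train"])
        model.n_validation_ = int(meta["n_validation"])
        model.validation_accuracy_ = float(meta["validation_accuracy"])
        model.training_meta_ = dict(meta)
        return model


def train_svm(data: LabeledFeatureSet, train_fraction: float = 0.70,
              max_iterations: int = 500, seed: int = 0, C: float = 1.0
              ) -> ViabilityClassifier:
    """Train the linear SVM with the stratified 70/30 protocol."""
    clf = ViabilityClassifier(C=C, max_iterations=max_iterations,
                              train_fraction=train_fraction, seed=seed)
    return clf.fit(data.X, data.labels)


def predict(model: ViabilityClassifier,
            features: GrainFeatures | np.ndarray) -> tuple[str, float]:
    """Classify one grain; returns (label, margin).  Margin 0 -> nonviable."""
    x = features.values if isinstance(features, GrainFeatures) else features
    margin = float(model.decision_function(np.asarray(x, dtype=np.float64)))
    return (VIABLE if margin > 0 else NONVIABLE), margin


def save_model(model: ViabilityClassifier, path: str | Path) -> None:
    """Write the model as versioned, human-inspectable JSON (deterministic)."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=True)


def load_model(path: str | Path) -> ViabilityClassifier:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    try:
        with open(path) as fh:
            d = json.load(fh)
        return ViabilityClassifier.from_dict(d)
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"corrupt model file {path}: {exc}") from exc
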