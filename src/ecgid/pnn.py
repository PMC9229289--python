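"""Probabilistic neural network (Parzen-window classifier).

The pattern layer stores every training exemplar; for input X the kernel

    phi_ij(X) = 1 / ((2 pi)^(1/2) delta^d) * exp(-||X - X_ij||^2 / delta^2)

is averaged within each class to give the summation-layer score g_i, and
the output layer reports argmax_i g_i. The constant and the ``delta^2``
(rather than ``2 delta^2``) exponent denominator are kept in this exact
form by default for fidelity to the formulation this package implements;
``standard_gaussian=True`` switches to the textbook multivariate kernel
``(2 pi)^(d/2) delta^d`` / ``2 delta^2``. Either way the constant is
class-independent, so predictions are identical (argmax is computed in the
log domain, which also keeps the small-delta nearest-neighbour limit
numerically exact).

The single hyperparameter, the smoothing factor delta, can be tuned by the
Whale Optimization Algorithm against a validation error
(:func:`tune_smoothing_factor`, :class:`WOAPNNClassifier`).
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from . import woa

__all__ = ["PNNClassifier", "WOAPNNClassifier", "EvalResult", "evaluate",
           "tune_smoothing_factor", "save_model", "load_model"]


class PNNClassifier(ClassifierMixin, BaseEstimator):
    """Probabilistic neural network classifier.

    Parameters
    ----------
    delta : float
        Smoothing factor (> 0): the Gaussian kernel width of the pattern
        layer. Small delta approaches 1-nearest-neighbour behaviour; large
        delta approaches predicting the most populous class.
    standard_gaussian : bool
        Use the textbook kernel normalisation and ``2 delta^2`` exponent
        denominator instead of the literal form above. Never changes the
        predicted labels.

    Attributes
    ----------
    classes_ : ndarray
        Ordered class labels; argmax ties break toward the earliest entry.
    X_ : ndarray of shape (n_exemplars, d)
        Stored training exemplars (lazy learner).
    class_counts_ : ndarray
        L, the exemplar count per class.
    """

    def __init__(self, delta: float = 1.0, standard_gaussian: bool = False):
        self.delta = delta
        self.standard_gaussian = standard_gaussian

    def fit(self, X, y):
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        X, y = validate_data(self, X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.X_ = np.asarray(X, dtype=float)
        self.y_idx_ = y_idx
        self.class_counts_ = np.bincount(y_idx, minlength=self.classes_.size)
        if np.any(self.class_counts_ == 0):
            raise ValueError("every class needs at least one exemplar")
        self.d_ = X.shape[1]
        return self

    def _denom(self) -> float:
        d2 = self.delta ** 2
        return 2.0 * d2 if self.standard_gaussian else d2

    def _log_const(self) -> float:
        d = self.d_
        if self.standard_gaussian:
            return -(d / 2.0) * math.log(2 * math.pi) - d * math.log(self.delta)
        return -0.5 * math.log(2 * math.pi) - d * math.log(self.delta)

    def _log_scores(self, X) -> np.ndarray:
        """log g_i per class, constant omitted (class-independent)."""
        sq = cdist(X, self.X_, metric="sqeuclidean")
        expo = -sq / self._denom()
        out = np.empty((X.shape[0], self.classes_.size))
        for k in range(self.classes_.size):
            cols = self.y_idx_ == k
            out[:, k] = logsumexp(expo[:, cols], axis=1) - math.log(
                int(self.class_counts_[k]))
        return out

    def class_scores(self, X) -> np.ndarray:
        """Summation-layer scores g_i(X), constant included.

        May underflow to 0 for tiny delta; classification always uses the
        log domain and is unaffected.
        """
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return np.exp(self._log_scores(X) + self._log_const())

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.classes_[np.argmax(self._log_scores(X), axis=1)]

    def predict_numeric(self, X) -> np.ndarray:
        """Predicted labels as floats (for MIV-style scalar outputs)."""
        return np.asarray(self.predict(X), dtype=float)


@dataclass
class EvalResult:
    """Evaluation of a fitted model on a test set."""

    error: float
    n: int
    y_pred: np.ndarray
    metric: str


def evaluate(model, X, y, metric: str = "misclassification_rate") -> EvalResult:
    """Test-set error under squared-label or 0/1 loss.

    ``eq_mse`` is the mean squared difference of numeric labels (subjects
    numbered from 0); ``misclassification_rate`` is the fraction wrong.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    y_pred = model.predict(X)
    if metric == "eq_mse":
        err = float(np.mean((np.asarray(y, float)
                             - np.asarray(y_pred, float)) ** 2))
    elif metric == "misclassification_rate":
        err = float(np.mean(y_pred != y))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return EvalResult(err, X.shape[0], y_pred, metric)


def tune_smoothing_factor(X_train, y_train, X_val, y_val,
                          woa_cfg: woa.WOAConfig | None = None,
                          fitness: str = "misclassification_rate",
                          standard_gaussian: bool = False):
    """WOA search for the smoothing factor delta.

    A 1-D whale swarm minimises the validation error of a PNN refit at each
    candidate delta. Returns ``(best_delta, history, model)`` with the
    model refit at the best delta.
    """
    woa_cfg = woa_cfg or woa.WOAConfig(bounds=[(0.01, 10.0)])
    if woa_cfg.dim != 1:
        raise ValueError("delta search is 1-D; give exactly one bound pair")
    X_train = np.asarray(X_train, float)
    X_val = np.asarray(X_val, float)

    def _fitness(pos):
        model = PNNClassifier(delta=float(pos[0]),
                              standard_gaussian=standard_gaussian)
        model.fit(X_train, y_train)
        return evaluate(model, X_val, y_val, metric=fitness).error

    best_pos, _, history = woa.optimize(_fitness, woa_cfg)
    best_delta = float(best_pos[0])
    model = PNNClassifier(delta=best_delta,
                          standard_gaussian=standard_gaussian)
    model.fit(X_train, y_train)
    return best_delta, history, model


class WOAPNNClassifier(ClassifierMixin, BaseEstimator):
    """PNN whose smoothing factor is tuned by the Whale Optimization
    Algorithm during ``fit``.

    Validation data may be passed to ``fit`` explicitly; otherwise the last
    ``val_fraction`` of each class's rows (by input order, deterministic)
    are held out for the search, and the final model is refit on all rows
    at the tuned delta.
    """

    def __init__(self, delta_bounds=(0.01, 10.0), pop_size: int = 10,
                 t_max: int = 100, b: float = 1.0,
                 fitness: str = "misclassification_rate",
                 val_fraction: float = 0.3, random_state: int | None = None,
                 standard_gaussian: bool = False):
        self.delta_bounds = delta_bounds
        self.pop_size = pop_size
        self.t_max = t_max
        self.b = b
        self.fitness = fitness
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.standard_gaussian = standard_gaussian

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = validate_data(self, X, y)
        y = np.asarray(y)
        if (X_val is None) != (y_val is None):
            raise ValueError("pass X_val and y_val together")
        if X_val is None:
            tr_idx, va_idx = [], []
            for cls in np.unique(y):
                rows = np.flatnonzero(y == cls)
                n_val = max(1, int(round(self.val_fraction * rows.size)))
                n_val = min(n_val, rows.size - 1) if rows.size > 1 else 0
                tr_idx.extend(rows[:rows.size - n_val])
                va_idx.extend(rows[rows.size - n_val:])
            if not va_idx:
                raise ValueError("not enough rows per class to hold out "
                                 "validation data")
            X_tr, y_tr = X[tr_idx], y[tr_idx]
            X_va, y_va = X[va_idx], y[va_idx]
        else:
            X_tr, y_tr = X, y
            X_va, y_va = np.asarray(X_val, float), np.asarray(y_val)
        cfg = woa.WOAConfig(bounds=[tuple(self.delta_bounds)],
                            pop_size=self.pop_size, t_max=self.t_max,
                            b=self.b, seed=self.random_state)
        self.delta_, self.history_, _ = tune_smoothing_factor(
            X_tr, y_tr, X_va, y_va, cfg, fitness=self.fitness,
            standard_gaussian=self.standard_gaussian)
        self.pnn_ = PNNClassifier(
            delta=self.delta_, standard_gaussian=self.standard_gaussian)
        self.pnn_.fit(X, y)
        self.classes_ = self.pnn_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.pnn_.predict(X)

    def class_scores(self, X):
        check_is_fitted(self)
        return self.pnn_.class_scores(X)


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: PNNClassifier, path) -> None:
    check_is_fitted(model)
    doc = {
        "delta": model.delta,
        "standard_gaussian": model.standard_gaussian,
        "d": int(model.d_),
        "classes": [c.item() if hasattr(c, "item") else c
                    for c in model.classes_],
        "exemplars": model.X_.tolist(),
        "exemplar_class_index": model.y_idx_.tolist(),
    }
    pathlib.Path(path).write_text(json.dumps(doc))


def load_model(path) -> PNNClassifier:
    doc = json.loads(pathlib.Path(path).read_text())
    model = PNNClassifier(delta=doc["delta"],
                          standard_gaussian=doc.get("standard_gaussian", False))
    X = np.asarray(doc["exemplars"], dtype=float)
    classes = np.asarray(doc["classes"])
    y = classes[np.asarray(doc["exemplar_class_index"], dtype=int)]
    model.fit(X, y)
    if model.d_ != doc["d"]:
        raise ValueError("model dimension mismatch in serialized file")
    return model
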