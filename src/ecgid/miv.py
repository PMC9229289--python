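"""Mean-impact-value (MIV) feature screening.

Each input variable i is scaled by (1 + alpha) and (1 - alpha) in turn;
the trained model is re-evaluated on both perturbed copies and the mean of
the per-sample output differences is the impact value I_MIV,i. Its sign
gives the direction of association and its magnitude the relative
importance; features with |I_MIV| above a cutoff are retained. For a
classifier the scalar model output defaults to the numeric predicted
label (subjects numbered from 0); the winning-class score is available as
an alternative output.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = ["MIVConfig", "MIVReport", "perturb", "compute_miv",
           "select_features", "MIVSelector"]


@dataclass
class MIVConfig:
    alpha: float = 0.10        # perturbation fraction
    threshold: float = 0.1     # |I_MIV| selection cutoff

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class MIVReport:
    """Signed impact values with ranking and selection mask."""

    miv: np.ndarray
    feature_names: list[str]
    alpha: float
    threshold: float

    def __post_init__(self) -> None:
        self.miv = np.asarray(self.miv, dtype=float).ravel()
        if len(self.feature_names) != self.miv.size:
            raise ValueError("one name per impact value required")

    @property
    def p(self) -> int:
        return self.miv.size

    @property
    def ranking(self) -> list[str]:
        """Feature names by |I_MIV| descending (stable for ties)."""
        order = np.argsort(-np.abs(self.miv), kind="stable")
        return [self.feature_names[i] for i in order]

    @property
    def selected(self) -> np.ndarray:
        return np.abs(self.miv) > self.threshold

    def to_json(self, path=None) -> str:
        doc = {"alpha": self.alpha, "threshold": self.threshold,
               "p": self.p,
               "miv": dict(zip(self.feature_names, self.miv.tolist())),
               "ranking": self.ranking,
               "selected": [n for n, s in zip(self.feature_names,
                                              self.selected) if s]}
        text = json.dumps(doc, indent=1)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text


def perturb(X, i: int, alpha: float, sign: str) -> np.ndarray:
    """Copy of X with column i scaled by (1 +/- alpha); others untouched."""
    X = np.asarray(X, dtype=float)
    if not 0 <= i < X.shape[1]:
        raise IndexError(f"feature index {i} out of range for p={X.shape[1]}")
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    out = X.copy()
    factor = 1.0 + alpha if sign == "+" else 1.0 - alpha
    out[:, i] *= factor
    return out


def compute_miv(predict_fn, X, cfg: MIVConfig | None = None,
                feature_names: list[str] | None = None) -> MIVReport:
    """Impact value per feature under a scalar-output model.

    ``predict_fn`` must return one finite numeric output per input row.
    """
    cfg = cfg or MIVConfig()
    X = np.asarray(X, dtype=float)
    m, p = X.shape
    names = feature_names if feature_names is not None else [
        f"x{i}" for i in range(p)]
    miv = np.empty(p)
    for i in range(p):
        y1 = np.asarray(predict_fn(perturb(X, i, cfg.alpha, "+")), float)
        y2 = np.asarray(predict_fn(perturb(X, i, cfg.alpha, "-")), float)
        if y1.shape != (m,) or y2.shape != (m,):
            raise ValueError("predict_fn must return one output per sample")
        iv = y1 - y2
        if not np.all(np.isfinite(iv)):
            raise ValueError(f"non-finite model output while perturbing "
                             f"feature {names[i]!r}")
        miv[i] = float(np.mean(iv))
    return MIVReport(miv, list(names), cfg.alpha, cfg.threshold)


def select_features(report: MIVReport,
                    threshold: float | None = None) -> list[str]:
    """Feature names with |I_MIV| > threshold, in ranking order."""
    thr = report.threshold if threshold is None else threshold
    by_abs = {n: a for n, a in zip(report.feature_names, np.abs(report.miv))}
    return [n for n in report.ranking if by_abs[n] > thr]


class MIVSelector(TransformerMixin, BaseEstimator):
    """Feature selector driven by mean impact values of a fitted model.

    Parameters
    ----------
    estimator : classifier with numeric labels
        Cloned and fitted on the training data; its numeric predicted
        label (or winning-class score with ``output='score'``) is the
        scalar output whose perturbation response is measured.
    alpha : float
        Perturbation fraction.
    threshold : float
        |I_MIV| cutoff; features at or below it are dropped.
    """

    def __init__(self, estimator, alpha: float = 0.10,
                 threshold: float = 0.1, output: str = "label"):
        self.estimator = estimator
        self.alpha = alpha
        self.threshold = threshold
        self.output = output

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        cfg = MIVConfig(alpha=self.alpha, threshold=self.threshold)
        est = clone(self.estimator).fit(X, y)
        if self.output == "label":
            def predict_fn(Z):
                return np.asarray(est.predict(Z), dtype=float)
        elif self.output == "score":
            def predict_fn(Z):
                return np.max(est.class_scores(Z), axis=1)
        else:
            raise ValueError("output must be 'label' or 'score'")
        self.report_ = compute_miv(predict_fn, X, cfg)
        self.miv_ = self.report_.miv
        self.support_ = self.report_.selected
        self.estimator_ = est
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self)
        return self.support_.copy()

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return X[:, self.support_]
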