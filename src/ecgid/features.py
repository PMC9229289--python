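"""Per-cycle characteristic vectors: 16 intervals plus 6 amplitudes.

Intervals are reported in seconds (sampling-rate independent, so features
pool across databases recorded at different rates); amplitudes are signed
differences in the signal's own units. The declared column order is fixed
by :data:`FEATURE_NAMES` and never changes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import Cycle, FiducialSet
from .signal import ECGSignal

__all__ = [
    "DISTANCE_FEATURES",
    "AMPLITUDE_FEATURES",
    "FEATURE_NAMES",
    "extract_features",
    "features_from_fiducials",
    "FeatureMatrix",
    "build_dataset",
    "majority_vote",
    "group_cycles",
    "grouped_accuracy",
]

log = logging.getLogger(__name__)

# point-name -> Cycle attribute
_POINTS = {"R": "r", "Q": "q", "S": "s", "P": "p_peak", "Pbegin": "p_on",
           "Pend": "p_off", "T": "t_peak", "Tbegin": "t_on", "Tend": "t_off"}

_DIST_PAIRS = [("R", "R"), ("R", "Q"), ("R", "S"), ("R", "P"), ("R", "T"),
               ("R", "Pbegin"), ("R", "Pend"), ("R", "Tbegin"), ("R", "Tend"),
               ("Q", "P"), ("Q", "Pbegin"), ("S", "T"), ("S", "Tend"),
               ("P", "T"), ("Pbegin", "Pend"), ("Tbegin", "Tend")]
_AMP_PAIRS = [("R", "Q"), ("R", "S"), ("Q", "P"), ("S", "T"),
              ("Pbegin", "P"), ("Tbegin", "T")]

DISTANCE_FEATURES = [f"dist_{a}-{b}" for a, b in _DIST_PAIRS]
AMPLITUDE_FEATURES = [f"amp_{a}-{b}" for a, b in _AMP_PAIRS]
FEATURE_NAMES = DISTANCE_FEATURES + AMPLITUDE_FEATURES
assert len(FEATURE_NAMES) == 22


def extract_features(cycle: Cycle, next_r: int, signal: ECGSignal) -> np.ndarray:
    """The 22-element characteristic vector for one complete cycle.

    Interval A-B is ``|index(A) - index(B)| / fs`` seconds; the R-R entry
    uses ``next_r`` (the following cycle's R). Amplitude A-B is
    ``x[A] - x[B]`` (signed).

    Raises
    ------
    ValueError
        If any fiducial is missing or R-R is non-positive.
    """
    if not cycle.is_complete():
        missing = [k for k, v in _POINTS.items()
                   if getattr(cycle, v) is None]
        raise ValueError(f"incomplete cycle: missing {missing}")
    fs = signal.fs
    x = signal.samples
    idx = {name: int(getattr(cycle, attr)) for name, attr in _POINTS.items()}
    rr = (int(next_r) - idx["R"]) / fs
    if rr <= 0:
        raise ValueError("R-R interval must be positive")
    vec = [rr]
    for a, b in _DIST_PAIRS[1:]:
        vec.append(abs(idx[a] - idx[b]) / fs)
    for a, b in _AMP_PAIRS:
        vec.append(x[idx[a]] - x[idx[b]])
    return np.array(vec)


def features_from_fiducials(fids: FiducialSet, signal: ECGSignal) -> np.ndarray:
    """Feature rows for every complete cycle of a recording.

    The last complete cycle has no successor; its R-R reuses the preceding
    R-R interval (or the recording mean when only one cycle exists).
    """
    cyc = fids.complete_cycles()
    if not cyc:
        return np.empty((0, len(FEATURE_NAMES)))
    rows = []
    for i, c in enumerate(cyc):
        if i + 1 < len(cyc):
            nxt = cyc[i + 1].r
        elif len(cyc) >= 2:
            nxt = c.r + (cyc[-1].r - cyc[-2].r)
        elif fids.mean_rr:
            nxt = c.r + int(round(fids.mean_rr))
        else:
            raise ValueError("cannot form R-R for a single-cycle recording "
                             "without a mean RR")
        rows.append(extract_features(c, nxt, signal))
    return np.vstack(rows)


@dataclass
class FeatureMatrix:
    """Feature rows with subject labels and the fixed column names."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.labels.shape[0]:
            raise ValueError("rows and labels length mismatch")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match feature_names")

    def __len__(self) -> int:
        return self.X.shape[0]

    def select(self, names) -> "FeatureMatrix":
        pos = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.X[:, pos], self.labels.copy(), list(names))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        if "label" not in df.columns:
            raise ValueError("feature CSV must contain a 'label' column")
        names = [c for c in df.columns if c != "label"]
        return cls(df[names].to_numpy(float), df["label"].to_numpy(), names)


def build_dataset(recordings, cycles_per_subject: int = 10,
                  cfg=None) -> FeatureMatrix:
    """Delineate and featurise labelled recordings into one matrix.

    Parameters
    ----------
    recordings : iterable of (label, ECGSignal) or (label, ECGSignal, FiducialSet)
        When a FiducialSet is supplied it is used as-is (e.g. simulator
        ground truth); otherwise the recording is delineated first.
    cycles_per_subject : int
        Number of leading complete cycles retained per recording. Subjects
        falling short keep what they have, with a logged warning.

    Rows are ordered by input order, then cycle order (deterministic).
    """
    from .detect import detect_fiducials

    blocks, labels = [], []
    for item in recordings:
        if len(item) == 3:
            label, signal, fids = item
        else:
            label, signal = item
            fids = detect_fiducials(signal, cfg)
        rows = features_from_fiducials(fids, signal)
        if rows.shape[0] < cycles_per_subject:
            log.warning("subject %r: only %d/%d complete cycles retained",
                        label, rows.shape[0], cycles_per_subject)
        rows = rows[:cycles_per_subject]
        blocks.append(rows)
        labels.extend([label] * rows.shape[0])
    X = np.vstack(blocks) if blocks else np.empty((0, len(FEATURE_NAMES)))
    return FeatureMatrix(X, np.asarray(labels), list(FEATURE_NAMES))


# ---------------------------------------------------------------------------
# Multi-cycle decisions


def majority_vote(votes) -> object:
    """Most frequent label; ties go to the earliest-seen label."""
    votes = list(votes)
    if not votes:
        raise ValueError("empty vote group")
    counts = Counter(votes)
    best = max(counts.values())
    for v in votes:
        if counts[v] == best:
            return v


def group_cycles(predictions, k: int = 3) -> list:
    """Majority label per consecutive non-overlapping group of ``k``.

    ``k=1`` reproduces the input. Raises if fewer than ``k`` predictions
    are available; a trailing partial group still votes with what it has.
    """
    preds = list(predictions)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(preds) < k:
        raise ValueError(f"need at least k={k} predictions, got {len(preds)}")
    return [majority_vote(preds[i:i + k]) for i in range(0, len(preds), k)]


def grouped_accuracy(y_true, y_pred, k: int = 3) -> float:
    """Accuracy of k-cycle majority decisions, grouping within each subject.

    Rows must be ordered so each subject's cycles are contiguous (the
    deterministic order :func:`build_dataset` produces).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    correct = total = 0
    start = 0
    for i in range(1, len(y_true) + 1):
        if i == len(y_true) or y_true[i] != y_true[start]:
            votes = group_cycles(y_pred[start:i], k)
            correct += sum(v == y_true[start] for v in votes)
            total += len(votes)
            start = i
    if total == 0:
        raise ValueError("empty prediction list")
    return correct / total
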