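"""Undecimated (à-trous) dyadic wavelet transform for ECG delineation.

The transform uses the classical quadratic-spline smoothing/derivative
filter pair standard in wavelet QRS delineation: low-pass ``[1,3,3,1]/8``
and high-pass ``[2,-2]``. At each dyadic stage j the filters are dilated by
inserting ``2**(j-1) - 1`` zeros between taps, so every detail signal
S1..S4 has the same length as the input and a sharp edge in the signal
appears as an opposite-sign modulus-maxima pair whose zero-crossing marks
the edge.

All filtering is causal (zero-lag convolution on a mirror-extended copy of
the input); the per-scale group delay needed to map a feature found on a
scale back to its time-domain sample is reported by :func:`scale_delay` and
stored on :class:`WaveletDecomposition`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal import ECGSignal

__all__ = [
    "WaveletDecomposition",
    "dyadic_swt",
    "scale_delay",
    "cascade_filter",
    "register_filter",
    "FILTERS",
]

# name -> (low-pass, high-pass) prototype filters (scale-1 taps)
FILTERS: dict[str, tuple[np.ndarray, np.ndarray]] = {
    "quadratic_spline": (np.array([1.0, 3.0, 3.0, 1.0]) / 8.0,
                         np.array([2.0, -2.0])),
}


def register_filter(name: str, lowpass, highpass) -> None:
    """Register an alternative smoothing/derivative filter pair."""
    lp = np.asarray(lowpass, dtype=float)
    hp = np.asarray(highpass, dtype=float)
    if lp.ndim != 1 or hp.ndim != 1 or lp.size < 2 or hp.size < 2:
        raise ValueError("filters must be 1-D with at least 2 taps")
    FILTERS[name] = (lp, hp)


def _get_filters(filter_name: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        return FILTERS[filter_name]
    except KeyError:
        raise ValueError(f"unknown wavelet filter {filter_name!r}; "
                         f"registered: {sorted(FILTERS)}") from None


def _upsample(f: np.ndarray, scale: int) -> np.ndarray:
    """À-trous dilation: insert ``2**(scale-1)-1`` zeros between taps."""
    step = 2 ** (scale - 1)
    if step == 1:
        return f
    out = np.zeros((f.size - 1) * step + 1)
    out[::step] = f
    return out


def cascade_filter(scale_index: int, filter_name: str = "quadratic_spline") -> np.ndarray:
    """Equivalent single filter producing scale ``scale_index`` directly.

    The scale-j detail equals the input convolved with
    ``g_j * h_{j-1} * ... * h_1`` (dilated filters); this is the brute-force
    reference the stage-wise transform must match.
    """
    if scale_index < 1:
        raise ValueError("scale_index must be >= 1")
    lp, hp = _get_filters(filter_name)
    q = _upsample(hp, scale_index)
    for j in range(scale_index - 1, 0, -1):
        q = np.convolve(q, _upsample(lp, j))
    return q


def scale_delay(scale_index: int, filter_name: str = "quadratic_spline") -> int:
    """Group delay (samples) of scale ``scale_index`` under causal filtering.

    Computed as the centroid of the absolute cascade impulse response,
    rounded half-up; subtracting it maps a feature located on a scale to its
    time-domain sample.
    """
    q = cascade_filter(scale_index, filter_name)
    w = np.abs(q)
    centroid = float(np.arange(q.size) @ w) / float(w.sum())
    return int(math.floor(centroid + 0.5))


@dataclass
class WaveletDecomposition:
    """Detail coefficients S1..S_num_scales aligned to the input signal.

    ``scales`` has shape ``(num_scales, n)``; ``scales[j-1]`` is Sj under the
    causal zero-lag convention, so a feature at time-domain sample ``n``
    appears on Sj near ``n + delays[j-1]``.
    """

    scales: np.ndarray
    delays: tuple[int, ...]
    filter_name: str
    fs: float

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        if self.scales.ndim != 2:
            raise ValueError("scales must be 2-D (num_scales, n)")
        if len(self.delays) != self.scales.shape[0]:
            raise ValueError("one delay per scale required")

    @property
    def num_scales(self) -> int:
        return self.scales.shape[0]

    def scale(self, j: int) -> np.ndarray:
        """Detail signal Sj (1-based)."""
        if not 1 <= j <= self.num_scales:
            raise ValueError(f"scale {j} not in 1..{self.num_scales}")
        return self.scales[j - 1]

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {"sample_index": np.arange(self.scales.shape[1])}
        for j in range(1, self.num_scales + 1):
            cols[f"S{j}"] = self.scales[j - 1]
        pd.DataFrame(cols).to_csv(path, index=False)


def dyadic_swt(signal: ECGSignal | np.ndarray, num_scales: int = 4,
               filter_name: str = "quadratic_spline",
               fs: float | None = None,
               extension: str = "mirror") -> WaveletDecomposition:
    """Undecimated dyadic wavelet transform (à-trous cascade).

    Parameters
    ----------
    signal : ECGSignal or 1-D array
        Input samples; arrays require ``fs`` only if downstream consumers
        need it (it is carried through, defaulting to 1.0).
    num_scales : int
        Number of detail scales to produce (>= 1, default 4).
    filter_name : str
        Key into the registered filter pairs.
    extension : str
        Boundary handling: ``"mirror"`` (default) reflects the signal;
        ``"edge"`` repeats the end values, which avoids fabricating
        reflected waves when transforming short local windows that may cut
        a steep slope.

    Raises
    ------
    ValueError
        If the signal is shorter than the deepest cascade filter or samples
        are non-finite.
    """
    if isinstance(signal, ECGSignal):
        x = signal.samples
        fs = signal.fs if fs is None else fs
    else:
        x = np.asarray(signal, dtype=float).ravel()
        if not np.all(np.isfinite(x)):
            raise ValueError("signal samples must be finite")
        fs = 1.0 if fs is None else fs
    if num_scales < 1:
        raise ValueError("num_scales must be >= 1")
    pad = cascade_filter(num_scales, filter_name).size
    if x.size <= pad + 1:
        raise ValueError(
            f"signal too short for {num_scales} scales: need > {pad + 1} "
            f"samples, got {x.size}")

    lp, hp = _get_filters(filter_name)
    # extend once by the deepest cascade length, filter stage-wise with
    # plain causal convolutions, then crop back to the input indices
    if extension == "mirror":
        xe = np.concatenate([x[1:pad + 1][::-1], x, x[-pad - 1:-1][::-1]])
    elif extension == "edge":
        xe = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    else:
        raise ValueError(f"unknown extension {extension!r}")
    approx = xe
    details = []
    for j in range(1, num_scales + 1):
        details.append(np.convolve(approx, _upsample(hp, j))[pad:pad + x.size])
        if j < num_scales:
            approx = np.convolve(approx, _upsample(lp, j))
    delays = tuple(scale_delay(j, filter_name) for j in range(1, num_scales + 1))
    return WaveletDecomposition(np.vstack(details), delays, filter_name, fs)
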