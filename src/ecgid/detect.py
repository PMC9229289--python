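"""Fiducial-point delineation on the dyadic wavelet scales.

R peaks are located on S4: adjacent opposite-sign modulus-maxima pairs
above a threshold bracket a zero-crossing which, after group-delay
correction, is refined to the raw-signal amplitude maximum. Q and S are
found by walking the fine scale S1 outward from each R and counting
modulus extrema. P and T are delineated with a *local windowed* wavelet
transform: a fresh 4-scale decomposition is computed on a short window
ahead of Q (behind S), so the transform never sees the dominant R peak;
the sub-threshold S4 minimum marks the wave peak, the preceding S4 maximum
its onset, and the offset mirrors the onset about the peak. Windows that
find nothing are translated outward in steps until the mean-RR bounds
(TR/2 ahead of Q, 2·TR/3 behind S) are exhausted.
"""

from __future__ import annotations

import json
import logging
import math
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import find_peaks

from .signal import ECGSignal
from .wavelet import WaveletDecomposition, dyadic_swt, scale_delay

__all__ = [
    "DetectionConfig",
    "Cycle",
    "FiducialSet",
    "detect_r_peaks",
    "mean_rr",
    "detect_qs",
    "detect_pt",
    "assemble_fiducials",
    "detect_fiducials",
    "match_indices",
]

log = logging.getLogger(__name__)

_CHAIN = ("p_on", "p_peak", "p_off", "q", "r", "s", "t_on", "t_peak", "t_off")
# pairs that may coincide (onset/peak/offset of the same low wave)
_NONSTRICT = {("p_on", "p_peak"), ("p_peak", "p_off"),
              ("t_on", "t_peak"), ("t_peak", "t_off")}


@dataclass
class DetectionConfig:
    """Tunable parameters of the delineator.

    Window lengths and the translation step are stored in seconds and
    resolved against the sampling rate (``*_samples`` helpers); explicit
    sample counts may be given instead via the ``*_samples`` override
    fields.
    """

    r_threshold_frac: float = 0.3      # fraction of max |S4| gating R pairs
    refractory_s: float = 0.2          # minimum R-R in seconds
    w_p_s: float = 0.20                # P search window length (s)
    w_t_s: float = 0.30                # T search window length (s)
    step_a_s: float = 0.02             # window translation per attempt (s)
    max_translations: int = 50         # cap on the translation count n
    pt_threshold_frac: float = 0.25    # fraction of in-window max |S4|
    pt_abs_floor_frac: float = 0.01    # in-window |S4| floor vs global max
    pt_onset_frac: float = 0.25        # onset max vs |peak min| balance
    qs_search_s: float = 0.12          # physiologic Q/S bound around R (s)
    refine_s: float = 0.06             # raw-signal refinement half-window (s)
    refine_smooth_s: float = 0.04      # P/T refinement moving-average (s)
    polarity: int = 1                  # -1 flips P/T (and R) polarity
    w_p: int | None = None             # explicit sample overrides
    w_t: int | None = None
    step_a: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold_frac <= 1:
            raise ValueError("r_threshold_frac must be in (0, 1]")
        if not 0 < self.pt_threshold_frac <= 1:
            raise ValueError("pt_threshold_frac must be in (0, 1]")
        if self.refractory_s <= 0:
            raise ValueError("refractory_s must be > 0")
        for name in ("w_p_s", "w_t_s", "step_a_s", "qs_search_s", "refine_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")

    def w_p_samples(self, fs: float) -> int:
        return self.w_p if self.w_p is not None else max(2, round(self.w_p_s * fs))

    def w_t_samples(self, fs: float) -> int:
        return self.w_t if self.w_t is not None else max(2, round(self.w_t_s * fs))

    def step_a_samples(self, fs: float) -> int:
        return self.step_a if self.step_a is not None else max(1, round(self.step_a_s * fs))


@dataclass
class Cycle:
    """Per-cycle fiducial sample indices (0-based); None marks undetected."""

    r: int
    q: int | None = None
    s: int | None = None
    p_on: int | None = None
    p_peak: int | None = None
    p_off: int | None = None
    t_on: int | None = None
    t_peak: int | None = None
    t_off: int | None = None

    def __post_init__(self) -> None:
        for name in _CHAIN:
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, int(v))

    def is_complete(self) -> bool:
        return all(getattr(self, k) is not None for k in _CHAIN)

    def in_order(self) -> bool:
        """Ordering invariant over the present fiducials."""
        prev_name, prev = None, None
        for name in _CHAIN:
            val = getattr(self, name)
            if val is None:
                continue
            if prev is not None:
                ok = val >= prev if (prev_name, name) in _NONSTRICT else val > prev
                if not ok:
                    return False
            prev_name, prev = name, val
        return True


@dataclass
class FiducialSet:
    """Delineation result for one recording."""

    cycles: list[Cycle]
    mean_rr: float | None
    fs: float
    index_base: int = 0
    n_excluded: int = 0

    def complete_cycles(self) -> list[Cycle]:
        return [c for c in self.cycles if c.is_complete()]

    def r_peaks(self) -> np.ndarray:
        return np.array([c.r for c in self.cycles], dtype=int)

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "index_base": self.index_base,
            "fs": self.fs,
            "mean_rr": self.mean_rr,
            "n_excluded": self.n_excluded,
            "cycles": [{"cycle": i, **asdict(c)}
                       for i, c in enumerate(self.cycles)],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FiducialSet":
        p = pathlib.Path(str(source))
        doc = json.loads(p.read_text() if p.exists() else source)
        cycles = []
        for c in doc["cycles"]:
            c = dict(c)
            c.pop("cycle", None)
            cycles.append(Cycle(**c))
        return cls(cycles, doc.get("mean_rr"), doc["fs"],
                   index_base=doc.get("index_base", 0),
                   n_excluded=doc.get("n_excluded", 0))

    def to_annotation_text(self) -> str:
        """WFDB-style annotation text: one ``sample<TAB>symbol`` per line."""
        sym = {"p_on": "(", "p_peak": "p", "p_off": ")", "q": "Q", "r": "N",
               "s": "S", "t_on": "(", "t_peak": "t", "t_off": ")"}
        rows = []
        for c in self.cycles:
            for name in _CHAIN:
                v = getattr(c, name)
                if v is not None:
                    rows.append((v, sym[name]))
        rows.sort()
        return "\n".join(f"{i}\t{s}" for i, s in rows) + ("\n" if rows else "")


# ---------------------------------------------------------------------------
# R peaks


def _signed_extrema(x: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Indices of local extrema of x with |x| > floor, sorted."""
    hi, _ = find_peaks(x)
    lo, _ = find_peaks(-x)
    idx = np.sort(np.concatenate([hi, lo]))
    if floor > 0:
        idx = idx[np.abs(x[idx]) > floor]
    return idx


def detect_r_peaks(decomp: WaveletDecomposition, signal: ECGSignal,
                   cfg: DetectionConfig | None = None) -> np.ndarray:
    """Locate R peaks via S4 modulus-maxima pairs.

    Returns strictly increasing sample indices; an empty array (not an
    error) when nothing crosses the threshold.
    """
    cfg = cfg or DetectionConfig()
    if decomp.scales.shape[1] != len(signal):
        raise ValueError("decomposition is not aligned to the signal")
    s4 = decomp.scale(4) * cfg.polarity
    x = signal.samples
    fs = signal.fs
    delay = decomp.delays[3]
    thr = cfg.r_threshold_frac * float(np.max(np.abs(s4)))
    if thr <= 0:
        return np.array([], dtype=int)
    ext = _signed_extrema(s4, floor=thr)
    half = max(1, round(0.100 * fs))  # +/-100 ms refinement window

    cands: list[tuple[int, float]] = []  # (r_index, modulus product)
    for a, b in zip(ext[:-1], ext[1:]):
        if s4[a] * s4[b] >= 0:
            continue
        seg = s4[a:b + 1]
        crossings = np.nonzero(seg[:-1] * seg[1:] <= 0)[0]
        if crossings.size == 0:
            continue
        k = int(crossings[0]) + a
        # sub-sample linear interpolation, then round
        denom = s4[k] - s4[k + 1]
        frac = s4[k] / denom if denom != 0 else 0.0
        zc = int(round(k + frac))
        t = zc - delay  # offset correction back to the time domain
        lo_i, hi_i = max(0, t - half), min(x.size, t + half + 1)
        if lo_i >= hi_i:
            continue
        r = lo_i + int(np.argmax(np.abs(x[lo_i:hi_i])))
        cands.append((r, float(abs(s4[a]) * abs(s4[b]))))

    if not cands:
        return np.array([], dtype=int)
    cands.sort()
    refractory = cfg.refractory_s * fs
    merged: list[tuple[int, float]] = []
    for r, m in cands:
        if merged and r - merged[-1][0] < refractory:
            if m > merged[-1][1]:
                merged[-1] = (r, m)
        else:
            merged.append((r, m))
    return np.array(sorted({r for r, _ in merged}), dtype=int)


def mean_rr(r_peaks) -> float:
    """Mean R-R interval TR in samples; requires >= 2 peaks."""
    r = np.asarray(r_peaks, dtype=float).ravel()
    if r.size < 2:
        raise ValueError("need at least 2 R peaks to compute mean RR")
    return float(np.mean(np.diff(r)))


# ---------------------------------------------------------------------------
# Q / S


def detect_qs(decomp: WaveletDecomposition, r_peaks,
              cfg: DetectionConfig | None = None,
              tr: float | None = None) -> tuple[list[int | None], list[int | None]]:
    """Q and S via the third |S1| modulus extremum out from each R.

    The walk is bounded by ``min(TR/2, qs_search_s * fs)``; when fewer than
    three extrema lie in-bound the outermost one found is used (smooth
    morphologies produce only the two QRS edge lobes on S1), and a cycle
    with no in-bound extrema gets None.
    """
    cfg = cfg or DetectionConfig()
    r_peaks = np.asarray(r_peaks, dtype=int).ravel()
    if r_peaks.size == 0:
        raise ValueError("r_peaks must be non-empty")
    s1 = decomp.scale(1)
    delay = decomp.delays[0]
    fs = decomp.fs
    n = s1.size
    if tr is None:
        tr = mean_rr(r_peaks) if r_peaks.size >= 2 else float(n)
    bound = int(min(0.5 * tr, cfg.qs_search_s * fs))
    # modulus maxima of S1 (peaks of |S1| with non-zero height)
    peaks, _ = find_peaks(np.abs(s1))
    ext = peaks[np.abs(s1[peaks]) > 0] - delay

    def _third(side: np.ndarray) -> int | None:
        if side.size == 0:
            return None
        take = min(3, side.size)
        return int(side[take - 1])

    qs, ss = [], []
    for r in r_peaks:
        left = ext[(ext >= r - bound) & (ext < r)]
        right = ext[(ext > r) & (ext <= r + bound)]
        qs.append(_third(left[::-1]))     # walk leftward from R
        ss.append(_third(right))          # walk rightward from R
    return qs, ss


# ---------------------------------------------------------------------------
# P / T (local windowed transform)


def _local_wave(x: np.ndarray, fs: float, start: int, stop: int,
                cfg: DetectionConfig, global_s4_max: float,
                filter_name: str) -> tuple[int, int] | None:
    """One windowed detection attempt; returns (peak, onset) or None.

    A fresh 1-4 scale transform is computed on ``x[start:stop]`` so the
    window never sees the R peak; the sub-threshold S4 minimum is the wave
    peak estimate and the preceding S4 maximum the onset estimate (both
    delay-corrected, window-relative).
    """
    start = max(0, start)
    stop = min(x.size, stop)
    win = x[start:stop] * cfg.polarity
    try:
        dec = dyadic_swt(win, num_scales=4, filter_name=filter_name,
                         fs=fs, extension="edge")
    except ValueError:
        return None  # truncated window too short for the cascade
    s4 = dec.scale(4)
    delay = dec.delays[3]
    m = float(np.max(np.abs(s4)))
    if m <= cfg.pt_abs_floor_frac * global_s4_max or m == 0.0:
        return None
    thr = cfg.pt_threshold_frac * m
    i_min = int(np.argmin(s4))
    if s4[i_min] >= -thr:
        return None  # nothing below the threshold: wave absent here
    if i_min == 0:
        return None
    # the onset is the rising-edge member of the wave's modulus-maxima
    # pair: the last local maximum before the minimum that is commensurate
    # with it. A global argmax would instead grab the (stronger) QRS
    # recovery upstroke whenever the window reaches back that far, and a
    # QRS downstroke cut at the window edge has no such maximum at all --
    # both cases are rejected so the window translates onward.
    head = s4[:i_min + 1]
    cand, _ = find_peaks(head)
    cand = cand[head[cand] >= cfg.pt_onset_frac * (-s4[i_min])]
    if cand.size == 0:
        return None
    i_on = int(cand[-1])
    peak = i_min - delay
    onset = i_on - delay
    peak = min(max(peak, 0), win.size - 1)
    onset = min(max(onset, 0), peak)
    return start + peak, start + onset


def _refine_peak(x: np.ndarray, est: int, half: int, polarity: int,
                 smooth: int = 1) -> int:
    """Raw-signal extremum near ``est``; P/T use a short moving average so
    wideband noise on the flat wave apex cannot drag the argmax."""
    lo = max(0, est - half)
    hi = min(x.size, est + half + 1)
    pad = smooth // 2
    seg_lo = max(0, lo - pad)
    seg = x[seg_lo:min(x.size, hi + pad)] * polarity
    if smooth > 1 and seg.size >= smooth:
        kernel = np.ones(smooth) / smooth
        seg = np.convolve(seg, kernel, mode="same")
    seg = seg[lo - seg_lo:lo - seg_lo + (hi - lo)]
    return lo + int(np.argmax(seg))


def detect_pt(signal: ECGSignal, q: list[int | None], s: list[int | None],
              tr: float, cfg: DetectionConfig | None = None,
              filter_name: str = "quadratic_spline",
              global_s4_max: float | None = None):
    """P and T delineation per cycle.

    For cycle i the P window covers the ``w_p`` samples ahead of ``q[i]``
    and translates left by ``step_a`` per attempt while
    ``w_p + a*n <= TR/2``; the T window covers ``w_t`` samples behind
    ``s[i]`` and translates right while ``w_t + a*n <= 2*TR/3``. The S4
    peak estimate is refined to the raw-signal extremum within
    ``+/-refine_s`` and the offset mirrors the onset about the peak.

    Returns ``(p_on, p_peak, p_off, t_on, t_peak, t_off)`` lists aligned to
    the input cycles, None where undetected.
    """
    cfg = cfg or DetectionConfig()
    x = signal.samples
    fs = signal.fs
    if global_s4_max is None:
        global_s4_max = float(np.max(np.abs(dyadic_swt(
            signal, 4, filter_name).scale(4))))
    w_p = cfg.w_p_samples(fs)
    w_t = cfg.w_t_samples(fs)
    a = cfg.step_a_samples(fs)
    half = max(1, round(cfg.refine_s * fs))
    smooth = max(1, round(cfg.refine_smooth_s * fs)) | 1

    p_on: list[int | None] = []
    p_peak: list[int | None] = []
    p_off: list[int | None] = []
    t_on: list[int | None] = []
    t_peak: list[int | None] = []
    t_off: list[int | None] = []

    def _search(anchor: int, wave: str):
        """Translate the window until a wave is found or bounds exhausted."""
        for n_tr in range(cfg.max_translations + 1):
            if wave == "P":
                if w_p + a * n_tr > tr / 2:
                    return None
                stop = anchor - a * n_tr
                startw = stop - w_p
            else:
                if w_t + a * n_tr > 2 * tr / 3:
                    return None
                startw = anchor + a * n_tr
                stop = startw + w_t
            if stop <= 0 or startw >= x.size:
                return None
            got = _local_wave(x, fs, startw, stop, cfg, global_s4_max,
                              filter_name)
            if got is not None:
                return got
        return None

    for qi, si in zip(q, s):
        if qi is None:
            p_on.append(None), p_peak.append(None), p_off.append(None)
        else:
            got = _search(int(qi), "P")
            if got is None:
                p_on.append(None), p_peak.append(None), p_off.append(None)
            else:
                pk_est, on = got
                pk = _refine_peak(x, pk_est, half, cfg.polarity, smooth)
                if on >= pk:
                    p_on.append(None), p_peak.append(None), p_off.append(None)
                else:
                    off = pk + (pk - on)
                    off = min(off, x.size - 1)
                    p_on.append(on), p_peak.append(pk), p_off.append(off)
        if si is None:
            t_on.append(None), t_peak.append(None), t_off.append(None)
        else:
            got = _search(int(si), "T")
            if got is None:
                t_on.append(None), t_peak.append(None), t_off.append(None)
            else:
                pk_est, on = got
                pk = _refine_peak(x, pk_est, half, cfg.polarity, smooth)
                if on >= pk:
                    t_on.append(None), t_peak.append(None), t_off.append(None)
                else:
                    off = pk + (pk - on)
                    off = min(off, x.size - 1)
                    t_on.append(on), t_peak.append(pk), t_off.append(off)
    return p_on, p_peak, p_off, t_on, t_peak, t_off


# ---------------------------------------------------------------------------
# Assembly


def assemble_fiducials(r_peaks, q, s, p, t, tr: float | None,
                       fs: float) -> FiducialSet:
    """Combine per-wave index lists into a FiducialSet.

    ``p`` and ``t`` are the (onset, peak, offset) triplets returned by
    :func:`detect_pt`. Cycles violating the ordering invariant are excluded
    (counted on ``n_excluded`` and logged), never repaired.
    """
    p_on, p_peak, p_off = p
    t_on, t_peak, t_off = t
    r_peaks = list(np.asarray(r_peaks, dtype=int).ravel())
    n = len(r_peaks)
    for name, lst in (("q", q), ("s", s), ("p_on", p_on), ("t_off", t_off)):
        if len(lst) != n:
            raise ValueError(f"{name} list not cycle-aligned with r_peaks")
    cycles, dropped = [], 0
    for i in range(n):
        c = Cycle(r=r_peaks[i], q=q[i], s=s[i],
                  p_on=p_on[i], p_peak=p_peak[i], p_off=p_off[i],
                  t_on=t_on[i], t_peak=t_peak[i], t_off=t_off[i])
        if c.in_order():
            cycles.append(c)
        else:
            dropped += 1
    if dropped:
        log.info("assemble_fiducials: excluded %d/%d cycles violating "
                 "ordering", dropped, n)
    return FiducialSet(cycles, tr, fs, n_excluded=dropped)


def detect_fiducials(signal: ECGSignal, cfg: DetectionConfig | None = None,
                     filter_name: str = "quadratic_spline") -> FiducialSet:
    """Full delineation pipeline: R -> TR -> Q/S -> P/T -> assembly."""
    cfg = cfg or DetectionConfig()
    decomp = dyadic_swt(signal, num_scales=4, filter_name=filter_name)
    r = detect_r_peaks(decomp, signal, cfg)
    if r.size == 0:
        return FiducialSet([], None, signal.fs)
    tr = mean_rr(r) if r.size >= 2 else float(len(signal))
    q, s = detect_qs(decomp, r, cfg, tr=tr)
    g4 = float(np.max(np.abs(decomp.scale(4))))
    p_on, p_peak, p_off, t_on, t_peak, t_off = detect_pt(
        signal, q, s, tr, cfg, filter_name, global_s4_max=g4)
    return assemble_fiducials(r, q, s, (p_on, p_peak, p_off),
                              (t_on, t_peak, t_off), tr, signal.fs)


# ---------------------------------------------------------------------------
# Scoring helper


def match_indices(detected, truth, tol: int) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to true indices within ``tol``.

    Returns ``(n_matched, n_detected, n_truth)`` from which recall and
    precision follow.
    """
    det = sorted(int(d) for d in np.asarray(detected).ravel())
    tru = sorted(int(t) for t in np.asarray(truth).ravel())
    i = j = matched = 0
    while i < len(det) and j < len(tru):
        d, t = det[i], tru[j]
        if abs(d - t) <= tol:
            matched += 1
            i += 1
            j += 1
        elif d < t:
            i += 1
        else:
            j += 1
    return matched, len(det), len(tru)
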