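"""Synthetic multi-subject ECG generator with exact fiducial ground truth.

Each subject is a template of five Gaussian bumps (P, Q, R, S, T) with
per-subject amplitudes, widths and latencies drawn once from physiological
ranges, plus a heart rate with small cycle-to-cycle jitter. Rendering sums
the bumps at jittered R times; ground-truth peak indices are the rendered
extrema of the *clean* signal and onsets/offsets sit two widths out from
each peak. Additive white noise (by SNR) and sinusoidal baseline wander
are applied only after the truth is recorded, so corrupting a recording
never alters its ground truth.

The Gaussian morphology is deliberate: detector scoring needs truth that
is exact by construction, not waveform realism. P and T are kept wider and
lower-slope than Q and S, as in real ECG, so the fine wavelet scale is
dominated by the QRS inside the physiologic Q/S search bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import Cycle, FiducialSet
from .signal import ECGSignal

__all__ = ["Wave", "SubjectTemplate", "SimOptions", "TEMPLATE_RANGES",
           "generate_subject", "render", "make_cohort", "CohortRecording"]

#: Physiological parameter ranges (uniform draws). Amplitudes in mV,
#: widths (Gaussian sigma) and latencies (center offset from R) in seconds.
TEMPLATE_RANGES: dict[str, tuple[float, float]] = {
    "p_amp": (0.10, 0.18),
    "p_sigma": (0.022, 0.028),
    "p_offset": (-0.22, -0.16),     # PR-style latency, P before R
    "q_amp": (-0.18, -0.10),
    "q_sigma": (0.007, 0.010),
    "q_offset": (-0.035, -0.025),
    "r_amp": (0.9, 1.6),
    "r_sigma": (0.010, 0.016),
    "r_offset": (0.0, 0.0),
    "s_amp": (-0.25, -0.10),
    "s_sigma": (0.007, 0.010),
    "s_offset": (0.025, 0.035),
    "t_amp": (0.15, 0.35),
    "t_sigma": (0.040, 0.050),
    "t_offset": (0.25, 0.32),
    "heart_rate": (55.0, 75.0),     # bpm
}

#: cycle-to-cycle R-R jitter, as a fraction of the nominal period
RR_JITTER_FRAC = 0.02


@dataclass
class Wave:
    amplitude: float   # mV
    width: float       # Gaussian sigma, seconds
    offset: float      # center relative to R, seconds


@dataclass
class SubjectTemplate:
    p: Wave
    q: Wave
    r: Wave
    s: Wave
    t: Wave
    heart_rate: float            # bpm
    rr_jitter: float = RR_JITTER_FRAC
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not (self.r.amplitude > abs(self.q.amplitude)
                and self.r.amplitude > abs(self.s.amplitude)):
            raise ValueError("R must dominate Q and S amplitudes")
        if not (self.p.offset < 0 < self.t.offset):
            raise ValueError("P and T must flank R")
        for w in (self.p, self.q, self.r, self.s, self.t):
            if w.width <= 0:
                raise ValueError("wave widths must be > 0")


@dataclass
class SimOptions:
    fs: float = 360.0
    n_cycles: int = 10
    noise_snr_db: float | None = None
    wander_amp: float = 0.0          # mV
    wander_freq: float = 0.33        # Hz
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")


def generate_subject(seed, subject_id: str = "") -> SubjectTemplate:
    """Draw one subject template; the same seed reproduces it exactly."""
    rng = np.random.default_rng(seed)
    draw = {k: rng.uniform(*TEMPLATE_RANGES[k])
            for k in sorted(TEMPLATE_RANGES)}
    waves = {w: Wave(draw[f"{w}_amp"] if w != "r" else draw["r_amp"],
                     draw[f"{w}_sigma"], draw[f"{w}_offset"])
             for w in ("p", "q", "r", "s", "t")}
    return SubjectTemplate(heart_rate=draw["heart_rate"],
                           subject_id=subject_id, **waves)


def _add_gaussian(out: np.ndarray, center: float, amp: float,
                  sigma_samp: float) -> None:
    lo = max(0, int(np.floor(center - 5 * sigma_samp)))
    hi = min(out.size, int(np.ceil(center + 5 * sigma_samp)) + 1)
    if lo >= hi:
        return
    n = np.arange(lo, hi)
    out[lo:hi] += amp * np.exp(-0.5 * ((n - center) / sigma_samp) ** 2)


def render(template: SubjectTemplate,
           opt: SimOptions | None = None) -> tuple[ECGSignal, FiducialSet]:
    """Render a recording and its ground-truth fiducials."""
    opt = opt or SimOptions()
    fs = opt.fs
    rng = np.random.default_rng(opt.seed)
    if opt.n_cycles == 0:
        empty = ECGSignal(np.zeros(2), fs, record_id=template.subject_id)
        return empty, FiducialSet([], None, fs)

    period = 60.0 / template.heart_rate * fs
    jit = rng.uniform(-template.rr_jitter, template.rr_jitter,
                      size=opt.n_cycles - 1) if opt.n_cycles > 1 else np.empty(0)
    periods = period * (1.0 + jit)
    lead = (-template.p.offset + 4 * template.p.width) * fs + 0.1 * fs
    r_times = lead + np.concatenate([[0.0], np.cumsum(periods)])
    tail = (template.t.offset + 4 * template.t.width) * fs + 0.1 * fs
    n = int(np.ceil(r_times[-1] + tail))

    clean = np.zeros(n)
    waves = {"p": template.p, "q": template.q, "r": template.r,
             "s": template.s, "t": template.t}
    for rt in r_times:
        for w in waves.values():
            _add_gaussian(clean, rt + w.offset * fs, w.amplitude,
                          w.width * fs)

    def _extremum(center: float, sigma_samp: float, sign: int) -> int:
        lo = max(0, int(np.floor(center - sigma_samp)))
        hi = min(n, int(np.ceil(center + sigma_samp)) + 1)
        seg = clean[lo:hi] * sign
        return lo + int(np.argmax(seg))

    cycles = []
    for rt in r_times:
        peak = {}
        for name, w in waves.items():
            c = rt + w.offset * fs
            peak[name] = _extremum(c, max(1.0, w.width * fs),
                                   1 if w.amplitude >= 0 else -1)
        dp = int(round(2 * template.p.width * fs))
        dt = int(round(2 * template.t.width * fs))
        cycles.append(Cycle(
            r=peak["r"], q=peak["q"], s=peak["s"],
            p_on=peak["p"] - dp, p_peak=peak["p"], p_off=peak["p"] + dp,
            t_on=peak["t"] - dt, t_peak=peak["t"], t_off=peak["t"] + dt))

    out = clean.copy()
    if opt.wander_amp:
        tgrid = np.arange(n) / fs
        out += opt.wander_amp * np.sin(
            2 * np.pi * opt.wander_freq * tgrid + rng.uniform(0, 2 * np.pi))
    if opt.noise_snr_db is not None:
        p_sig = float(np.mean(clean ** 2))
        p_noise = p_sig / 10 ** (opt.noise_snr_db / 10.0)
        out += rng.normal(0.0, np.sqrt(p_noise), size=n)

    truth = FiducialSet(cycles, float(np.mean(periods)) if periods.size else None, fs)
    return ECGSignal(out, fs, record_id=template.subject_id), truth


@dataclass
class CohortRecording:
    label: int
    signal: ECGSignal
    truth: FiducialSet
    template: SubjectTemplate


def make_cohort(n_subjects: int, cycles_per_subject: int = 10,
                opt: SimOptions | None = None,
                seed: int | None = None) -> list[CohortRecording]:
    """Deterministic labelled cohort; labels are 0..n_subjects-1.

    Subject seeds are spawned from the master seed (``seed`` argument, or
    ``opt.seed``), so the whole cohort is reproducible byte-for-byte.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    opt = opt or SimOptions()
    master = seed if seed is not None else opt.seed
    ss = np.random.SeedSequence(master)
    children = ss.spawn(n_subjects)
    recordings = []
    for label, child in enumerate(children):
        tmpl_ss, render_ss = child.spawn(2)
        template = generate_subject(tmpl_ss, subject_id=f"subj{label:03d}")
        o = SimOptions(fs=opt.fs, n_cycles=cycles_per_subject,
                       noise_snr_db=opt.noise_snr_db,
                       wander_amp=opt.wander_amp,
                       wander_freq=opt.wander_freq, seed=render_ss)
        sig, truth = render(template, o)
        recordings.append(CohortRecording(label, sig, truth, template))
    return recordings
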