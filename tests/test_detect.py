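"""Fiducial delineation: R/Q/S/P/T against simulator ground truth."""

import numpy as np
import pytest

from ecgid.detect import (Cycle, DetectionConfig, FiducialSet,
                          assemble_fiducials, detect_fiducials, detect_pt,
                          detect_qs, detect_r_peaks, match_indices, mean_rr)
from ecgid.signal import ECGSignal
from ecgid.simulate import SimOptions, generate_subject, render
from ecgid.wavelet import WaveletDecomposition, dyadic_swt


def test_flat_signal_yields_no_r_peaks():
    sig = ECGSignal(np.zeros(3600), 360.0)
    r = detect_r_peaks(dyadic_swt(sig), sig)
    assert r.size == 0


def test_single_gaussian_bump_located_within_one_sample():
    fs = 360.0
    n = np.arange(3600)
    sig = ECGSignal(np.exp(-0.5 * ((n - 1000) / 5.0) ** 2), fs)
    r = detect_r_peaks(dyadic_swt(sig), sig)
    assert r.size == 1
    assert abs(int(r[0]) - 1000) <= 1  # oracle: argmax at 1000


def test_r_peaks_on_clean_recording_match_truth_exactly():
    template = generate_subject(11, "s")
    sig, truth = render(template, SimOptions(seed=12))
    r = detect_r_peaks(dyadic_swt(sig), sig)
    truth_r = [c.r for c in truth.cycles]
    assert r.size == len(truth_r)
    assert all(abs(a - b) <= 3 for a, b in zip(r, truth_r))


def test_mean_rr_arithmetic():
    assert mean_rr([0, 100, 200]) == 100
    assert mean_rr([0, 100, 220]) == 110
    with pytest.raises(ValueError, match="at least 2"):
        mean_rr([42])


def test_mean_rr_matches_configured_cycle_length():
    template = generate_subject(21, "s")
    template.heart_rate = 60.0
    sig, truth = render(template, SimOptions(fs=360.0, seed=3))
    r = detect_r_peaks(dyadic_swt(sig), sig)
    assert abs(mean_rr(r) - 360.0) <= 360.0 * template.rr_jitter + 2


def _decomp_with_s1(s1: np.ndarray, fs: float = 360.0) -> WaveletDecomposition:
    scales = np.zeros((4, s1.size))
    scales[0] = s1
    return WaveletDecomposition(scales, (1, 3, 7, 15), "quadratic_spline", fs)


def test_qs_hand_built_extrema_walk():
    # |S1| extrema whose delay-corrected offsets from R are -4, -9, -15
    # (and +4, +9, +15): the third one out is Q (S).
    r = 500
    s1 = np.zeros(1000)
    for off in (-4, -9, -15, 4, 9, 15):
        s1[r + off + 1] = 1.0  # +1 undoes the scale-1 delay correction
    q, s = detect_qs(_decomp_with_s1(s1), [r], tr=400.0)
    assert q == [r - 15]
    assert s == [r + 15]


def test_qs_missing_when_no_extrema():
    q, s = detect_qs(_decomp_with_s1(np.zeros(1000)), [500], tr=400.0)
    assert q == [None] and s == [None]


def test_qs_on_clean_recording_close_to_truth():
    template = generate_subject(31, "s")
    sig, truth = render(template, SimOptions(seed=32))
    dec = dyadic_swt(sig)
    r = detect_r_peaks(dec, sig)
    q, s = detect_qs(dec, r, tr=mean_rr(r))
    for qi, si, c in zip(q, s, truth.cycles):
        assert qi is not None and abs(qi - c.q) <= 5
        assert si is not None and abs(si - c.s) <= 5


def test_pt_missing_on_flat_segments_without_error():
    fs = 360.0
    x = np.zeros(3600)
    x[1000] = 1.0  # lone spike, flat everywhere else
    sig = ECGSignal(x, fs)
    p_on, p_peak, p_off, t_on, t_peak, t_off = detect_pt(
        sig, [995], [1005], tr=360.0)
    assert p_peak == [None] and t_peak == [None]


def test_pt_on_clean_recording_within_five_samples():
    template = generate_subject(41, "s")
    sig, truth = render(template, SimOptions(seed=42))
    fids = detect_fiducials(sig)
    assert len(fids.cycles) == len(truth.cycles)
    for d, c in zip(fids.cycles, truth.cycles):
        assert d.p_peak is not None and abs(d.p_peak - c.p_peak) <= 5
        assert d.t_peak is not None and abs(d.t_peak - c.t_peak) <= 5


def test_offset_mirrors_onset_about_peak():
    template = generate_subject(51, "s")
    sig, _ = render(template, SimOptions(seed=52))
    for c in detect_fiducials(sig).cycles:
        if c.t_off is not None and c.t_off < len(sig) - 1:
            assert c.t_off - c.t_peak == c.t_peak - c.t_on
        if c.p_off is not None:
            assert c.p_off - c.p_peak == c.p_peak - c.p_on


def test_assemble_keeps_consistent_and_drops_misordered():
    ok = dict(q=[90, 190], s=[110, 210],
              p=([50, 150], [60, 160], [70, 170]),
              t=([130, 230], [140, 240], [150, 250]))
    fids = assemble_fiducials([100, 200], ok["q"], ok["s"], ok["p"], ok["t"],
                              tr=100.0, fs=360.0)
    assert len(fids.cycles) == 2 and fids.n_excluded == 0

    bad_s = [110, 195]  # second cycle: s < r
    fids2 = assemble_fiducials([100, 200], ok["q"], bad_s, ok["p"], ok["t"],
                               tr=100.0, fs=360.0)
    assert len(fids2.cycles) == 1 and fids2.n_excluded == 1
    assert fids2.cycles[0].r == 100


def test_every_emitted_cycle_satisfies_ordering(clean_detections):
    for fids in clean_detections:
        for c in fids.cycles:
            assert c.in_order()


def test_detection_shift_equivariance():
    template = generate_subject(61, "s")
    sig, _ = render(template, SimOptions(seed=62))
    shift = 251
    shifted = ECGSignal(np.concatenate([np.zeros(shift), sig.samples]),
                        sig.fs)
    base = detect_fiducials(sig)
    moved = detect_fiducials(shifted)
    # compare interior cycles (skip first/last, which feel the boundary)
    names = ("p_on", "p_peak", "p_off", "q", "r", "s", "t_on", "t_peak",
             "t_off")
    for b, m in list(zip(base.cycles, moved.cycles))[1:-1]:
        for name in names:
            vb, vm = getattr(b, name), getattr(m, name)
            assert vb is not None and vm is not None
            assert vm - vb == shift


def test_fiducials_json_roundtrip(tmp_path, clean_detections):
    fids = clean_detections[0]
    path = tmp_path / "f.json"
    fids.to_json(path)
    back = FiducialSet.from_json(path)
    assert back.fs == fids.fs
    assert back.mean_rr == fids.mean_rr
    assert [c.__dict__ for c in back.cycles] == [c.__dict__
                                                 for c in fids.cycles]


def test_annotation_text_is_sorted_and_complete(clean_detections):
    text = clean_detections[0].to_annotation_text()
    rows = [ln.split("\t") for ln in text.strip().splitlines()]
    idx = [int(r[0]) for r in rows]
    assert idx == sorted(idx)
    assert sum(1 for r in rows if r[1] == "N") == len(
        clean_detections[0].cycles)


def test_match_indices_counts():
    assert match_indices([10, 50, 90], [11, 52, 200], tol=3) == (2, 3, 3)
    assert match_indices([], [5], tol=3) == (0, 0, 1)
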