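"""Characteristic-vector construction and multi-cycle voting."""

import numpy as np
import pytest

from ecgid.detect import Cycle, FiducialSet
from ecgid.features import (AMPLITUDE_FEATURES, DISTANCE_FEATURES,
                            FEATURE_NAMES, FeatureMatrix, build_dataset,
                            extract_features, features_from_fiducials,
                            group_cycles, grouped_accuracy, majority_vote)
from ecgid.signal import ECGSignal
from ecgid.simulate import SimOptions, generate_subject, render


def _toy_cycle(base: int = 0) -> Cycle:
    return Cycle(r=base + 1000, q=base + 980, s=base + 1020,
                 p_on=base + 880, p_peak=base + 900, p_off=base + 920,
                 t_on=base + 1100, t_peak=base + 1140, t_off=base + 1180)


def _toy_signal(n: int = 3000, fs: float = 500.0) -> ECGSignal:
    rng = np.random.default_rng(9)
    return ECGSignal(rng.normal(size=n), fs)


def test_feature_name_layout():
    assert len(FEATURE_NAMES) == 22
    assert len(DISTANCE_FEATURES) == 16
    assert len(AMPLITUDE_FEATURES) == 6
    assert FEATURE_NAMES[0] == "dist_R-R"


def test_rq_distance_hand_example():
    sig = _toy_signal()
    vec = extract_features(_toy_cycle(), next_r=1500, signal=sig)
    # R=1000, Q=980 at 500 Hz -> 20 samples = 0.04 s
    assert vec[FEATURE_NAMES.index("dist_R-Q")] == pytest.approx(0.04)


def test_identical_offsets_give_identical_vectors():
    sig = ECGSignal(np.tile(np.sin(np.linspace(0, 2 * np.pi, 500)), 6), 500.0)
    v1 = extract_features(_toy_cycle(0), 1500, sig)
    v2 = extract_features(_toy_cycle(500), 2000, sig)
    np.testing.assert_array_equal(v1, v2)


def test_all_22_values_match_hand_recomputation():
    """Spreadsheet-style oracle: recompute each entry from the index map."""
    sig = _toy_signal()
    x, fs = sig.samples, sig.fs
    c = _toy_cycle()
    vec = extract_features(c, next_r=1470, signal=sig)
    pts = {"R": c.r, "Q": c.q, "S": c.s, "P": c.p_peak, "Pbegin": c.p_on,
           "Pend": c.p_off, "T": c.t_peak, "Tbegin": c.t_on, "Tend": c.t_off}
    expected = {"dist_R-R": (1470 - c.r) / fs}
    for name in DISTANCE_FEATURES[1:]:
        a, b = name.removeprefix("dist_").split("-", 1)
        expected[name] = abs(pts[a] - pts[b]) / fs
    for name in AMPLITUDE_FEATURES:
        a, b = name.removeprefix("amp_").split("-", 1)
        expected[name] = x[pts[a]] - x[pts[b]]
    for i, name in enumerate(FEATURE_NAMES):
        assert vec[i] == pytest.approx(expected[name], abs=1e-12), name


def test_incomplete_cycle_rejected_with_reason():
    c = _toy_cycle()
    c.t_peak = None
    with pytest.raises(ValueError, match="missing.*T"):
        extract_features(c, 1500, _toy_signal())


def test_last_cycle_reuses_previous_rr():
    sig = _toy_signal(6000)
    fids = FiducialSet([_toy_cycle(0), _toy_cycle(1400)], 1400.0, sig.fs)
    rows = features_from_fiducials(fids, sig)
    assert rows.shape == (2, 22)
    assert rows[0, 0] == pytest.approx(1400 / sig.fs)
    assert rows[1, 0] == pytest.approx(1400 / sig.fs)


def test_time_shift_leaves_features_unchanged():
    template = generate_subject(71, "s")
    sig, truth = render(template, SimOptions(seed=72))
    rows = features_from_fiducials(truth, sig)
    shift = 100
    sig2 = ECGSignal(np.concatenate([np.zeros(shift), sig.samples]), sig.fs)
    moved = FiducialSet(
        [Cycle(**{k: v + shift for k, v in c.__dict__.items()})
         for c in truth.cycles], truth.mean_rr, truth.fs)
    rows2 = features_from_fiducials(moved, sig2)
    np.testing.assert_allclose(rows, rows2, atol=1e-12)


def test_amplitude_scaling_touches_only_amplitude_features():
    template = generate_subject(73, "s")
    sig, truth = render(template, SimOptions(seed=74))
    rows = features_from_fiducials(truth, sig)
    sig3 = ECGSignal(sig.samples * 3.0, sig.fs)
    rows3 = features_from_fiducials(truth, sig3)
    np.testing.assert_allclose(rows3[:, :16], rows[:, :16], atol=1e-12)
    np.testing.assert_allclose(rows3[:, 16:], 3.0 * rows[:, 16:], rtol=1e-12)


def test_build_dataset_counts_and_shortfall(caplog):
    template = generate_subject(75, "s")
    sig, truth = render(template, SimOptions(n_cycles=4, seed=76))
    import logging

    with caplog.at_level(logging.WARNING, logger="ecgid.features"):
        fm = build_dataset([("a", sig, truth)], cycles_per_subject=10)
    assert len(fm) == 4
    assert "4/10" in caplog.text

    empty = build_dataset([], cycles_per_subject=10)
    assert len(empty) == 0 and empty.X.shape == (0, 22)


def test_feature_csv_roundtrip_is_exact(tmp_path):
    template = generate_subject(77, "s")
    sig, truth = render(template, SimOptions(seed=78))
    fm = build_dataset([(3, sig, truth)], cycles_per_subject=10)
    path = tmp_path / "f.csv"
    fm.to_csv(path)
    back = FeatureMatrix.from_csv(path)
    np.testing.assert_array_equal(back.X, fm.X)
    assert back.feature_names == fm.feature_names
    assert list(back.labels) == list(fm.labels)


def test_majority_vote_and_grouping():
    assert majority_vote(["A", "A", "B"]) == "A"
    assert majority_vote(["B", "A"]) == "B"  # tie -> earliest seen
    assert group_cycles([1, 1, 2, 3, 3, 3], k=3) == [1, 3]
    assert group_cycles([5, 6, 7], k=1) == [5, 6, 7]
    with pytest.raises(ValueError, match="at least k"):
        group_cycles([1, 2], k=3)


def test_grouped_accuracy_beats_single_when_votes_help():
    """Enumeration oracle: per-subject majority over the prediction list."""
    y_true = np.repeat([0, 1, 2], 9)
    rng = np.random.default_rng(13)
    y_pred = y_true.copy()
    # corrupt 2 of 9 cycles per subject: single-cycle acc 7/9, vote acc 1.0
    for s in range(3):
        idx = rng.choice(np.flatnonzero(y_true == s), size=2, replace=False)
        y_pred[idx] = (y_true[idx] + 1) % 3
    single = float(np.mean(y_pred == y_true))
    grouped = grouped_accuracy(y_true, y_pred, k=9)
    assert grouped >= single
    assert grouped == 1.0
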