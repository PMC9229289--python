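"""PNN kernel arithmetic, limit behaviour and WOA tuning."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.base import clone

from ecgid.pnn import (PNNClassifier, WOAPNNClassifier, evaluate, load_model,
                       save_model, tune_smoothing_factor)
from ecgid.woa import WOAConfig


def _two_class_1d():
    return np.array([[0.0], [1.0]]), np.array([0, 1])


def test_fit_bookkeeping():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(10, 22))
    y = np.repeat([0, 1], 5)
    m = PNNClassifier().fit(X, y)
    assert m.d_ == 22
    assert list(m.class_counts_) == [5, 5]
    m2 = PNNClassifier().fit(X, y)
    np.testing.assert_array_equal(m.X_, m2.X_)


def test_pattern_layer_size_at_seventy_percent_split():
    # 156 subjects x 7 training cycles -> 1092 stored exemplars
    X = np.zeros((156 * 7, 3))
    y = np.repeat(np.arange(156), 7)
    m = PNNClassifier().fit(X + np.arange(len(y))[:, None], y)
    assert m.X_.shape[0] == 1092


def test_hand_evaluated_score_ratio_is_exp_two():
    X, y = _two_class_1d()
    m = PNNClassifier(delta=0.5).fit(X, y)
    g = m.class_scores(np.array([[0.25]]))
    assert g[0, 0] / g[0, 1] == pytest.approx(np.exp(2.0), abs=1e-10)
    assert m.predict(np.array([[0.25]]))[0] == 0


def test_scores_nonnegative_and_argmax_is_label():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(30, 4))
    y = rng.integers(0, 3, 30)
    m = PNNClassifier(delta=0.8).fit(X, y)
    Xt = rng.normal(size=(10, 4))
    g = m.class_scores(Xt)
    assert np.all(g >= 0)
    np.testing.assert_array_equal(m.predict(Xt),
                                  m.classes_[np.argmax(g, axis=1)])


def test_exact_tie_breaks_to_first_class():
    X = np.array([[-1.0], [1.0]])
    y = np.array([3, 7])
    m = PNNClassifier(delta=1.0).fit(X, y)
    assert m.predict(np.array([[0.0]]))[0] == 3


def test_small_delta_limit_equals_nearest_neighbour():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(50, 2))
    y = rng.integers(0, 5, 50)
    Xt = rng.normal(size=(50, 2))
    nn = y[np.argmin(cdist(Xt, X), axis=1)]
    m = PNNClassifier(delta=1e-9).fit(X, y)
    np.testing.assert_array_equal(m.predict(Xt), nn)


def test_large_delta_limit_minimises_mean_squared_distance():
    """Within-class averaging cancels class priors, so for huge delta the
    winner is the class whose exemplars have the smallest mean squared
    distance to the input (second-order expansion of the kernel)."""
    rng = np.random.default_rng(8)
    X = rng.normal(size=(30, 2))
    y = np.array([0] * 20 + [1] * 10)
    m = PNNClassifier(delta=1e4).fit(X, y)
    Xt = rng.normal(size=(20, 2)) * 3
    sq = cdist(Xt, X, "sqeuclidean")
    oracle = np.array([np.argmin([sq[i, y == k].mean() for k in (0, 1)])
                       for i in range(len(Xt))])
    np.testing.assert_array_equal(m.predict(Xt), oracle)


def test_constant_and_exponent_convention_never_change_predictions():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(40, 5))
    y = rng.integers(0, 4, 40)
    Xt = rng.normal(size=(25, 5))
    for delta in (0.3, 1.0, 3.0):
        lit = PNNClassifier(delta=delta).fit(X, y)
        std = PNNClassifier(delta=delta / np.sqrt(2),
                            standard_gaussian=True).fit(X, y)
        np.testing.assert_array_equal(lit.predict(Xt), std.predict(Xt))


def test_well_separated_gaussians_high_accuracy():
    rng = np.random.default_rng(10)
    c0, c1 = np.zeros(2), np.array([4.0, 0.0])
    X = np.vstack([rng.normal(c0, 0.5, (200, 2)),
                   rng.normal(c1, 0.5, (200, 2))])
    y = np.repeat([0, 1], 200)
    Xt = np.vstack([rng.normal(c0, 0.5, (200, 2)),
                    rng.normal(c1, 0.5, (200, 2))])
    yt = np.repeat([0, 1], 200)
    for delta in (0.1, 0.5, 1.0, 2.0):
        m = PNNClassifier(delta=delta).fit(X, y)
        assert np.mean(m.predict(Xt) == yt) >= 0.99


def test_invalid_inputs_raise():
    X, y = _two_class_1d()
    with pytest.raises(ValueError, match="delta"):
        PNNClassifier(delta=0.0).fit(X, y)
    m = PNNClassifier().fit(X, y)
    with pytest.raises(ValueError):
        m.predict(np.zeros((3, 5)))  # dimension mismatch


def test_evaluate_metrics_arithmetic():
    class Fixed:
        def predict(self, X):
            return np.array([0, 1, 0])

    res = evaluate(Fixed(), np.zeros((3, 1)), np.array([0, 1, 2]),
                   metric="eq_mse")
    assert res.error == pytest.approx(4 / 3)
    res2 = evaluate(Fixed(), np.zeros((3, 1)), np.array([0, 1, 2]))
    assert res2.error == pytest.approx(1 / 3)
    assert res.error >= res2.error  # squared integer gaps >= 0/1 loss
    with pytest.raises(ValueError, match="empty"):
        evaluate(Fixed(), np.zeros((0, 1)), np.array([]))


def test_perfect_predictions_zero_error():
    X, y = _two_class_1d()
    m = PNNClassifier(delta=0.1).fit(X, y)
    assert evaluate(m, X, y, "eq_mse").error == 0.0
    assert evaluate(m, X, y).error == 0.0


def _cluster_data(seed, n_classes=6, per=12, d=4, spread=0.3):
    rng = np.random.default_rng(seed)
    centers = rng.normal(scale=3.0, size=(n_classes, d))
    X = np.vstack([rng.normal(c, spread, (per, d)) for c in centers])
    y = np.repeat(np.arange(n_classes), per)
    return X, y


def test_tuning_single_class_validation_returns_immediately_valid_delta():
    X, y = _two_class_1d()
    Xv = np.array([[0.1], [0.2]])
    yv = np.array([0, 0])
    cfg = WOAConfig(bounds=[(0.01, 10.0)], pop_size=4, t_max=3, seed=2)
    delta, history, model = tune_smoothing_factor(X, y, Xv, yv, cfg)
    assert history[0] == 0.0
    assert 0.01 <= delta <= 10.0


def test_tuned_delta_no_worse_than_fixed_unit_delta():
    X, y = _cluster_data(3)
    Xv, yv = _cluster_data(4)
    cfg = WOAConfig(bounds=[(0.01, 10.0)], pop_size=10, t_max=30, seed=5)
    delta, history, model = tune_smoothing_factor(X, y, Xv, yv, cfg)
    tuned = evaluate(model, Xv, yv).error
    fixed = evaluate(PNNClassifier(delta=1.0).fit(X, y), Xv, yv).error
    assert tuned <= fixed
    assert all(a >= b for a, b in zip(history, history[1:]))


def test_woapnn_estimator_fit_predict_and_clone():
    X, y = _cluster_data(6)
    est = WOAPNNClassifier(pop_size=4, t_max=5, random_state=0)
    clone(est)  # sklearn param contract
    est.fit(X, y)
    assert est.delta_ > 0
    assert np.mean(est.predict(X) == y) > 0.9


def test_model_json_roundtrip(tmp_path):
    X, y = _cluster_data(12)
    m = PNNClassifier(delta=0.7).fit(X, y)
    path = tmp_path / "model.json"
    save_model(m, path)
    back = load_model(path)
    Xt, _ = _cluster_data(13)
    np.testing.assert_array_equal(back.predict(Xt), m.predict(Xt))
    assert back.delta == m.delta
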