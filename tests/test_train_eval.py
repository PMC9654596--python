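"""Metric identities of the evaluation report and training-loop contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegemotion.classifier import EmotionClassifier
from eegemotion.nn import Dense, Network, Softmax
from eegemotion.train import EvalReport, TrainConfig, evaluate, train

counts = st.integers(0, 10_000)


# ------------------------------------------------------------------ metrics

@given(tp=counts, fp=counts, tn=counts, fn=counts)
@settings(max_examples=300, derandomize=True)
def test_metric_identities_hold_for_any_counts(tp, fp, tn, fn):
    """Accuracy, precision, recall and F1 follow their defining ratios
    exactly (rational arithmetic), for every non-degenerate denominator."""
    if tp + fp + tn + fn == 0:
        return
    rep = EvalReport.from_counts([tp], [fp], [tn], [fn])
    assert rep.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn), abs=0)
    if tp + fp > 0:
        assert rep.precision[0] == pytest.approx(tp / (tp + fp), abs=0)
    if tp + fn > 0:
        assert rep.recall[0] == pytest.approx(tp / (fn + tp), abs=0)
    p, r = rep.precision[0], rep.recall[0]
    if p + r > 0 and "precision" not in rep.undefined[0] \
            and "recall" not in rep.undefined[0]:
        assert rep.f1[0] == pytest.approx(2 * p * r / (p + r))
        # harmonic <= geometric <= arithmetic mean of (precision, recall)
        assert rep.f1[0] <= np.sqrt(p * r) + 1e-12
        assert np.sqrt(p * r) <= (p + r) / 2 + 1e-12
        assert min(p, r) - 1e-12 <= rep.f1[0] <= (p + r) / 2 + 1e-12


def test_hand_worked_confusion_case():
    rep = EvalReport.from_counts([1, 1], [1, 1], [1, 1], [1, 1])
    assert rep.accuracy == 0.5
    assert rep.precision == [0.5, 0.5]
    assert rep.recall == [0.5, 0.5]
    assert rep.f1 == [0.5, 0.5]


def test_perfect_predictor_scores_one():
    y = np.array([0, 1, 0, 1, 1, 0])
    rep = EvalReport.from_predictions(y, y)
    assert rep.accuracy == 1.0
    assert rep.precision == [1.0, 1.0]
    assert rep.recall == [1.0, 1.0]
    assert rep.f1 == [1.0, 1.0]
    assert rep.support == [3, 3]


def test_undefined_precision_flagged_not_dropped():
    # class 0 never predicted: TP=0, FP=0
    rep = EvalReport.from_counts([0, 5], [0, 3], [5, 0], [3, 0])
    assert rep.precision[0] == 0.0
    assert "precision" in rep.undefined[0]
    assert rep.undefined[1] == ()


def test_accuracy_agrees_with_error_rate(rng):
    y_true = rng.integers(0, 2, 500)
    y_pred = rng.integers(0, 2, 500)
    rep = EvalReport.from_predictions(y_true, y_pred)
    assert rep.accuracy == pytest.approx(1 - np.mean(y_true != y_pred), abs=0)
    assert sum(rep.support) == 500


def test_evaluate_rejects_empty_set(rng):
    net = Network([Dense(2, 3, rng), Softmax()])
    with pytest.raises(ValueError, match="empty"):
        evaluate(net, np.empty((0, 3)), np.empty((0, 2)))


# ----------------------------------------------------------------- training

def test_zero_epochs_is_a_no_op(rng):
    net = Network([Dense(2, 4, rng), Softmax()])
    before = net.get_weights()
    trace = train(net, rng.standard_normal((10, 4)), np.eye(2)[[0, 1] * 5],
                  config=TrainConfig(epochs=0))
    assert trace.n_epochs == 0 and trace.val_accuracy == []
    for b, a in zip(before, net.get_weights()):
        np.testing.assert_array_equal(b, a)


def test_non_finite_loss_aborts_with_diagnostics(rng):
    net = Network([Dense(2, 4, rng), Softmax()])
    x = rng.standard_normal((10, 4))
    x[3, 2] = np.inf
    with pytest.raises(RuntimeError, match="non-finite"):
        train(net, x, np.eye(2)[[0, 1] * 5], config=TrainConfig(epochs=1))


def test_training_learns_separable_toy_data(rng):
    x = np.vstack([rng.normal(-1.5, 0.4, (60, 6)), rng.normal(1.5, 0.4, (60, 6))])
    y = np.eye(2)[np.array([0] * 60 + [1] * 60)]
    net = Network([Dense(2, 6, rng), Softmax()])  # shallow but sufficient
    trace = train(net, x, y, x, y,
                  TrainConfig(epochs=5, batch_size=16, learning_rate=0.05, seed=0))
    assert trace.n_epochs == 5
    assert len(trace.val_accuracy) == 5
    assert trace.val_accuracy[-1] > 0.9


def test_classifier_records_split_and_trace(tiny_recording):
    clf = EmotionClassifier.from_recordings([tiny_recording],
                                            window_size=256, step=64)
    res = clf.fit(variant="C1D2", epochs=2, seed=0)
    assert res.trace.n_epochs == 2
    assert len(clf.train_idx) + len(clf.test_idx) == clf.features.n_windows
    assert res.n_params == 18_706
    text = res.summary()
    assert "C1D2" in text and "test accuracy" in text
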