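"""Training loop and evaluation metrics for the CNN classifiers.

Training follows the reference protocol: Adam, categorical
cross-entropy, batch size 100, up to 100 epochs, with the held-out test
set doubling as the per-epoch validation set (an optional three-way
split is available by passing a distinct validation set).  Evaluation
reports per-class one-vs-rest confusion counts and the derived accuracy,
precision, recall and F1, computed in exact rational arithmetic before
the final float conversion.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .nn import Adam, Network, softmax_cross_entropy

__all__ = ["TrainConfig", "TrainTrace", "EvalReport", "train", "evaluate"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters (defaults follow the study protocol)."""

    epochs: int = 100
    batch_size: int = 100
    learning_rate: float = 1e-3
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")


@dataclass
class TrainTrace:
    """Per-epoch history for accuracy-curve plots."""

    train_accuracy: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    loss: list = field(default_factory=list)
    epoch_seconds: list = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.loss)

    @property
    def final_val_accuracy(self) -> float | None:
        return self.val_accuracy[-1] if self.val_accuracy else None

    @property
    def best_val_accuracy(self) -> float | None:
        return max(self.val_accuracy) if self.val_accuracy else None


def _accuracy(model: Network, x, y_onehot) -> float:
    return float(np.mean(model.predict(x) == y_onehot.argmax(axis=1)))


def train(model: Network, x_train, y_train, x_val=None, y_val=None,
          config: TrainConfig = TrainConfig()) -> TrainTrace:
    """Mini-batch Adam training; returns the per-epoch trace.

    With ``epochs=0`` the model is untouched and the trace is empty.
    Aborts with ``RuntimeError`` if the loss turns non-finite.
    """
    trace = TrainTrace()
    if config.epochs == 0:
        return trace
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    n = x_train.shape[0]
    for epoch in range(config.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        epoch_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            probs = model.forward(x_train[idx], training=True)
            loss, grad = softmax_cross_entropy(probs, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // config.batch_size}: "
                    f"loss={loss}; consider lowering the learning rate"
                )
            epoch_loss += loss * len(idx)
            model.backward(grad)
            opt.step(model.grads())
        trace.loss.append(epoch_loss / n)
        trace.train_accuracy.append(_accuracy(model, x_train, y_train))
        if x_val is not None:
            trace.val_accuracy.append(_accuracy(model, x_val, y_val))
        trace.epoch_seconds.append(time.perf_counter() - t0)
    return trace


@dataclass
class EvalReport:
    """Per-class one-vs-rest confusion counts and derived metrics.

    ``precision``, ``recall`` and ``f1`` are per-class lists (class 0,
    class 1); a zero denominator yields 0.0 with the class flagged in
    ``undefined``.  ``accuracy`` is the overall fraction correct.
    """

    tp: list
    fp: list
    tn: list
    fn: list
    accuracy: float
    precision: list
    recall: list
    f1: list
    support: list
    undefined: list

    @classmethod
    def from_counts(cls, tp, fp, tn, fn) -> "EvalReport":
        """Build a report from per-class one-vs-rest confusion counts."""
        n_cls = len(tp)
        precision, recall, f1, support, undefined = [], [], [], [], []
        for c in range(n_cls):
            flags = []
            p = (Fraction(tp[c], tp[c] + fp[c]) if tp[c] + fp[c] > 0
                 else flags.append("precision") or Fraction(0))
            r = (Fraction(tp[c], tp[c] + fn[c]) if tp[c] + fn[c] > 0
                 else flags.append("recall") or Fraction(0))
            f = (2 * p * r / (p + r) if p + r > 0
                 else flags.append("f1") or Fraction(0))
            precision.append(float(p))
            recall.append(float(r))
            f1.append(float(f))
            support.append(tp[c] + fn[c])
            undefined.append(tuple(flags))
        total = tp[0] + fp[0] + tn[0] + fn[0]
        acc = float(Fraction(tp[0] + tn[0], total)) if total else 0.0
        return cls(list(tp), list(fp), list(tn), list(fn),
                   acc, precision, recall, f1, support, undefined)

    @classmethod
    def from_predictions(cls, y_true, y_pred, n_classes: int = 2) -> "EvalReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        tp, fp, tn, fn = [], [], [], []
        for c in range(n_classes):
            t = y_true == c
            p = y_pred == c
            tp.append(int(np.sum(t & p)))
            fp.append(int(np.sum(~t & p)))
            tn.append(int(np.sum(~t & ~p)))
            fn.append(int(np.sum(t & ~p)))
        return cls.from_counts(tp, fp, tn, fn)

    def summary(self, label: str = "") -> str:
        head = f"classification report{' — ' + label if label else ''}"
        lines = [head, f"{'class':>6} {'precision':>10} {'recall':>8} "
                       f"{'f1':>8} {'support':>9}"]
        for c in range(len(self.tp)):
            lines.append(
                f"{c:>6} {self.precision[c]:>10.4f} {self.recall[c]:>8.4f} "
                f"{self.f1[c]:>8.4f} {self.support[c]:>9,}"
            )
        lines.append(f"accuracy {self.accuracy:.4f} on {sum(self.support):,} rows")
        return "\n".join(lines)


def evaluate(model: Network, x, y_onehot) -> EvalReport:
    """Confusion counts + metrics of a trained model on labeled tensors."""
    if x.shape[0] == 0:
        raise ValueError("empty evaluation set")
    y_true = y_onehot.argmax(axis=1)
    y_pred = model.predict(x)
    return EvalReport.from_predictions(y_true, y_pred, y_onehot.shape[1])
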