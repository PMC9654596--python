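"""High-level Model/Results interface over the pipeline.

``EmotionClassifier`` bundles the standard preparation chain — rating
feature extension, column standardization, binarization, train/test
split, tensor reshape — around a chosen CNN variant, in the fit/Results
style of statistical modelling packages:

>>> model = EmotionClassifier.from_recordings(recs, target="valence",
...                                           extension="fe-3")
>>> res = model.fit(variant="M2", epochs=10)
>>> print(res.summary())

The Results object carries the trained network, the per-epoch accuracy
trace, the held-out evaluation report and the configuration needed to
replay the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import (
    ExtensionMode, LabelSpec, SplitSpec, extend_features, split_indices,
    to_model_tensors,
)
from .models import VARIANTS, build_model, count_params
from .spectral import (
    DEFAULT_BANDS, DEFAULT_STEP, DEFAULT_WINDOW, FeatureMatrix,
    extract_features, standardize,
)
from .train import EvalReport, TrainConfig, TrainTrace, evaluate, train

__all__ = ["EmotionClassifier", "EmotionClassifierResults"]


class EmotionClassifier:
    """Binary valence/arousal classifier over band-power features.

    Parameters
    ----------
    features : FeatureMatrix
        Raw (unstandardized) spectral features with per-window ratings.
    target : {"valence", "arousal"}
    extension : {"none", "fe-l", "fe-l-d", "fe-3"}
        Complementary-rating columns appended to the spectral features.
    split : SplitSpec
        Train/test protocol (default 75/25, window-row unit).
    standardize_on : {"all", "train"}
        Fit column statistics on the full matrix before splitting (the
        reference protocol, which leaks test statistics into training and
        is documented as such) or on the training rows only.
    """

    def __init__(self, features: FeatureMatrix, target: str = "valence",
                 extension: str = "fe-3", split: SplitSpec = SplitSpec(),
                 standardize_on: str = "all"):
        if standardize_on not in ("all", "train"):
            raise ValueError("standardize_on must be 'all' or 'train'")
        self.raw_features = features
        self.target = target
        self.extension = ExtensionMode(extension, target)
        self.label_spec = LabelSpec(target)
        self.split = split
        self.standardize_on = standardize_on
        self._prepare()

    @classmethod
    def from_recordings(cls, recordings, target: str = "valence",
                        extension: str = "fe-3",
                        window_size: int = DEFAULT_WINDOW,
                        step: int = DEFAULT_STEP, bands=DEFAULT_BANDS,
                        channels=None, row_stride: int = 1, **kw):
        """Extract features from recordings and build the classifier.

        ``row_stride`` keeps every k-th feature row — a problem-size
        control for fast experiments; 1 keeps everything.
        """
        mats = [
            extract_features(r, channels=channels, bands=bands,
                             window_size=window_size, step=step)
            for r in recordings
        ]
        feats = FeatureMatrix.concat(mats)
        if row_stride > 1:
            keep = np.arange(0, feats.n_windows, row_stride)
            feats = _take_rows(feats, keep)
        return cls(feats, target=target, extension=extension, **kw)

    def _prepare(self):
        extended = extend_features(self.raw_features, self.extension)
        n = extended.n_windows
        self.train_idx, self.test_idx = split_indices(
            n, self.split,
            trial_key=_trial_group_key(extended) if self.split.unit == "trial" else None,
        )
        if self.standardize_on == "all":
            scaled, self.scaler = standardize(extended)
        else:
            train_view = _take_rows(extended, self.train_idx)
            _, self.scaler = standardize(train_view)
            scaled, _ = standardize(extended, scaler=self.scaler)
        self.features = scaled
        x, y = to_model_tensors(scaled, self.label_spec)
        self.x_train, self.y_train = x[self.train_idx], y[self.train_idx]
        self.x_test, self.y_test = x[self.test_idx], y[self.test_idx]

    @property
    def input_width(self) -> int:
        return self.features.n_features

    def fit(self, variant: str = "M2", config: TrainConfig | None = None,
            epochs: int | None = None, seed: int = 0) -> "EmotionClassifierResults":
        """Train a CNN variant; returns a Results object.

        ``epochs`` overrides the config default; the held-out test set
        serves as the per-epoch validation set.
        """
        if config is None:
            config = TrainConfig(seed=seed)
        if epochs is not None:
            config = TrainConfig(epochs=epochs, batch_size=config.batch_size,
                                 learning_rate=config.learning_rate,
                                 seed=config.seed, shuffle=config.shuffle)
        network = build_model(variant, self.input_width, seed=config.seed)
        trace = train(network, self.x_train, self.y_train,
                      self.x_test, self.y_test, config)
        report = evaluate(network, self.x_test, self.y_test)
        train_report = evaluate(network, self.x_train, self.y_train)
        return EmotionClassifierResults(
            model=self, variant=variant, network=network, config=config,
            trace=trace, eval_report=report, train_report=train_report,
        )


def _take_rows(m: FeatureMatrix, idx) -> FeatureMatrix:
    from dataclasses import replace
    return replace(
        m, values=m.values[idx], ratings=m.ratings[idx],
        trial_index=m.trial_index[idx], start_offset=m.start_offset[idx],
        participant_id=m.participant_id[idx],
    )


def _trial_group_key(m: FeatureMatrix) -> np.ndarray:
    return np.char.add(m.participant_id.astype(str),
                       np.char.mod("/%d", m.trial_index))


@dataclass
class EmotionClassifierResults:
    """Trained classifier with its history and held-out evaluation."""

    model: EmotionClassifier
    variant: str
    network: object
    config: TrainConfig
    trace: TrainTrace
    eval_report: EvalReport
    train_report: EvalReport
    extra: dict = field(default_factory=dict)

    @property
    def test_accuracy(self) -> float:
        return self.eval_report.accuracy

    @property
    def train_accuracy(self) -> float:
        return self.train_report.accuracy

    @property
    def n_params(self) -> int:
        return count_params(self.network)

    def predict(self, x) -> np.ndarray:
        return self.network.predict(x)

    def summary(self) -> str:
        v = VARIANTS[self.variant]
        m = self.model
        lines = [
            f"EmotionClassifier results — {v.describe()}",
            f"target {m.target}, extension {m.extension.mode}, "
            f"input width {m.input_width}",
            f"trainable parameters: {self.n_params:,}",
            f"train rows {len(m.train_idx):,} / test rows {len(m.test_idx):,} "
            f"(fraction {m.split.train_fraction}, unit {m.split.unit}, "
            f"seed {m.split.seed})",
            f"epochs run: {self.trace.n_epochs} "
            f"(batch {self.config.batch_size}, lr {self.config.learning_rate}, "
            f"seed {self.config.seed})",
            f"train accuracy {self.train_accuracy:.4f} / "
            f"test accuracy {self.test_accuracy:.4f}",
            "",
            self.eval_report.summary("held-out test set"),
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Train/validation accuracy per epoch (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, self.trace.n_epochs + 1)
        ax.plot(epochs, self.trace.train_accuracy, label="train")
        if self.trace.val_accuracy:
            ax.plot(epochs, self.trace.val_accuracy, label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("accuracy")
        ax.set_title(f"{self.variant} on {self.model.target}")
        ax.legend()
        return ax
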