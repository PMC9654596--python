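"""Experiment harnesses: window-size and train-split sweeps.

Two kinds of function live here.  The ``*_table`` functions are pure
windowing arithmetic — they compute the train/test sample sizes implied
by a window size and split fraction without touching any data, so the
full 32-participant bookkeeping can be checked in microseconds.  The
``run_*`` functions actually train and evaluate a CNN per sweep point on
supplied recordings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .classifier import EmotionClassifier
from .dataset import SplitSpec, binarize_rating
from .spectral import DEFAULT_STEP, plan_windows
from .train import TrainConfig

__all__ = [
    "WINDOW_SIZES",
    "SPLIT_FRACTIONS",
    "window_size_table",
    "split_size_table",
    "run_window_sweep",
    "run_split_sweep",
    "accuracy_trend_rank_correlation",
]

#: Window sizes of the EEG-length study, in samples at 128 Hz.
WINDOW_SIZES = (4, 8, 16, 32, 64, 128, 256, 512, 1024)

#: Train fractions of the training-size study.
SPLIT_FRACTIONS = (0.8, 0.75, 0.5, 0.2, 0.1)


def window_size_table(n_participants: int = 32, n_trials: int = 40,
                      trial_length: int = 8064, step: int = DEFAULT_STEP,
                      sample_rate: float = 128.0,
                      windows=WINDOW_SIZES,
                      train_fraction: float = 0.75) -> pd.DataFrame:
    """Sample-size bookkeeping per window size (no data required).

    Columns: window, time_slice_s, windows_per_trial, total, train, test.
    ``train = round(train_fraction * total)`` and ``test = total - train``.
    """
    rows = []
    for w in windows:
        per_trial = plan_windows(trial_length, w, step).n_windows
        total = n_participants * n_trials * per_trial
        train = int(round(train_fraction * total))
        rows.append({
            "window": w,
            "time_slice_s": w / sample_rate,
            "windows_per_trial": per_trial,
            "total": total,
            "train": train,
            "test": total - train,
        })
    return pd.DataFrame(rows)


def split_size_table(n_total: int, fractions=SPLIT_FRACTIONS) -> pd.DataFrame:
    """Train/test sizes for each split fraction of ``n_total`` rows."""
    rows = []
    for f in fractions:
        train = int(round(f * n_total))
        rows.append({"train_fraction": f, "train": train, "test": n_total - train})
    return pd.DataFrame(rows)


def run_window_sweep(recordings, windows=WINDOW_SIZES, variant: str = "M2",
                     target: str = "valence", extension: str = "fe-3",
                     config: TrainConfig | None = None,
                     split: SplitSpec = SplitSpec(), row_stride: int = 1,
                     standardize_on: str = "all") -> pd.DataFrame:
    """Train/evaluate one classifier per window size.

    Returns a table with the window, its time slice in seconds, the
    train/test sizes actually used, final train/test accuracy, and the
    seeds, for replay.
    """
    config = config or TrainConfig()
    rows = []
    for w in windows:
        clf = EmotionClassifier.from_recordings(
            recordings, target=target, extension=extension, window_size=w,
            split=split, row_stride=row_stride, standardize_on=standardize_on,
        )
        res = clf.fit(variant=variant, config=config)
        rows.append({
            "window": w,
            "time_slice_s": w / recordings[0].sample_rate,
            "train_size": len(clf.train_idx),
            "test_size": len(clf.test_idx),
            "train_accuracy": res.train_accuracy,
            "test_accuracy": res.test_accuracy,
            "epochs": res.trace.n_epochs,
            "train_seed": config.seed,
            "split_seed": split.seed,
        })
    return pd.DataFrame(rows)


def run_split_sweep(features, fractions=SPLIT_FRACTIONS, variant: str = "M2",
                    target: str = "valence", extension: str = "fe-3",
                    config: TrainConfig | None = None, split_seed: int = 0,
                    standardize_on: str = "all") -> pd.DataFrame:
    """Train/evaluate one classifier per train/test split fraction.

    ``features`` is a raw FeatureMatrix (spectral columns + ratings).
    The table reports per-class train/test counts and final accuracies.
    """
    config = config or TrainConfig()
    rows = []
    for f in fractions:
        clf = EmotionClassifier(
            features, target=target, extension=extension,
            split=SplitSpec(train_fraction=f, seed=split_seed),
            standardize_on=standardize_on,
        )
        res = clf.fit(variant=variant, config=config)
        y_all = binarize_rating(clf.features.rating(target))
        y_tr, y_te = y_all[clf.train_idx], y_all[clf.test_idx]
        rows.append({
            "train_fraction": f,
            "train_class0": int(np.sum(y_tr == 0)),
            "train_class1": int(np.sum(y_tr == 1)),
            "test_class0": int(np.sum(y_te == 0)),
            "test_class1": int(np.sum(y_te == 1)),
            "train_accuracy": res.train_accuracy,
            "test_accuracy": res.test_accuracy,
            "train_seed": config.seed,
            "split_seed": split_seed,
        })
    return pd.DataFrame(rows)


def accuracy_trend_rank_correlation(sweep: pd.DataFrame) -> float:
    """Spearman rank correlation between window size and test accuracy.

    A value near 1 means accuracy is (noisily) non-decreasing in the
    window size — longer EEG slices resolve the frequency bands better.
    """
    rho, _ = spearmanr(sweep["window"], sweep["test_accuracy"])
    return float(rho)
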