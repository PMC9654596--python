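"""Turning feature matrices into model-ready tensors.

Covers label binarization (rating < 5 -> class 0, >= 5 -> class 1),
one-hot encoding, the rating feature extension (appending a trial's
complementary self-assessment scores as extra input columns), seeded
train/test splitting, and the reshape to the (n, width, 1) layout the
1-D convolutional models consume.

The feature extension deliberately feeds the *other* ratings to the
classifier; the prediction target itself is structurally excluded.  The
split defaults to window-row granularity, which places windows of the
same trial on both sides — an optimistic-evaluation protocol that this
module reproduces faithfully and also lets you avoid via trial-level
splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import RATING_NAMES
from .spectral import FeatureMatrix

__all__ = [
    "ExtensionMode",
    "EXTENSION_MODES",
    "LabelSpec",
    "SplitSpec",
    "binarize_rating",
    "one_hot",
    "extend_features",
    "split_indices",
    "to_model_tensors",
]

#: Feature-extension modes: which complementary ratings are appended.
#: FE-3 appends the three ratings other than the prediction target.
EXTENSION_MODES = ("none", "fe-l", "fe-l-d", "fe-3")


@dataclass(frozen=True)
class ExtensionMode:
    """Resolved extension: the ordered rating names to append."""

    mode: str
    target: str

    def __post_init__(self):
        if self.mode not in EXTENSION_MODES:
            raise ValueError(f"mode must be one of {EXTENSION_MODES}, got {self.mode!r}")
        if self.target not in ("valence", "arousal"):
            raise ValueError(f"target must be valence or arousal, got {self.target!r}")

    @property
    def appended(self) -> tuple:
        if self.mode == "none":
            return ()
        if self.mode == "fe-l":
            return ("liking",)
        if self.mode == "fe-l-d":
            return ("liking", "dominance")
        # fe-3: the three ratings other than the target, in the fixed
        # (valence, arousal, dominance, liking) rating order.
        return tuple(r for r in RATING_NAMES if r != self.target)


@dataclass(frozen=True)
class LabelSpec:
    """Binary label rule on a 1-9 rating: [1, 5) -> 0, [5, 9] -> 1."""

    target: str = "valence"
    threshold: float = 5.0

    def __post_init__(self):
        if self.target not in ("valence", "arousal"):
            raise ValueError(f"target must be valence or arousal, got {self.target!r}")


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split: fraction, seed, and unit of assignment.

    ``unit="window-row"`` shuffles and splits individual windows (the
    protocol behind the printed split sizes); ``unit="trial"`` keeps all
    windows of a trial on one side, avoiding within-trial leakage.
    """

    train_fraction: float = 0.75
    seed: int = 0
    unit: str = "window-row"

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )
        if self.unit not in ("window-row", "trial"):
            raise ValueError(f"unit must be 'window-row' or 'trial', got {self.unit!r}")


def binarize_rating(rating) -> np.ndarray:
    """Map ratings to classes: < 5 -> 0, >= 5 -> 1.  Scalar in, scalar out."""
    r = np.asarray(rating, dtype=np.float64)
    if np.any((r < 1.0) | (r > 9.0)):
        raise ValueError(f"rating outside [1, 9]: {r[(r < 1.0) | (r > 9.0)][:5]}"
                         if r.ndim else f"rating outside [1, 9]: {r}")
    label = (r >= 5.0).astype(np.int64)
    return label if label.ndim else label.item()


def one_hot(labels, n_classes: int = 2) -> np.ndarray:
    """Indicator encoding; each row sums to 1."""
    labels = np.asarray(labels, dtype=np.int64)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels.ravel()] = 1.0
    return out


def extend_features(matrix: FeatureMatrix, mode: ExtensionMode) -> FeatureMatrix:
    """Append complementary-rating columns to the feature matrix.

    The appended set never contains the prediction target.  Widths for
    the default 70 spectral columns become 70/71/72/73 for
    none/FE-L/FE-L-D/FE-3.  Idempotence is not attempted: extending an
    already-extended matrix raises.
    """
    if matrix.extension:
        raise ValueError("matrix already carries extension columns")
    appended = mode.appended
    if not appended:
        return replace(matrix, extension=())
    cols = [matrix.rating(name)[:, None] for name in appended]
    return replace(
        matrix,
        values=np.hstack([matrix.values] + cols),
        feature_names=list(matrix.feature_names) + [f"rating_{n}" for n in appended],
        extension=appended,
    )


def split_indices(n_total: int, spec: SplitSpec, trial_key=None):
    """Disjoint, exhaustive train/test index arrays.

    Train size is ``round(train_fraction * n_total)`` exactly.  With
    ``unit="trial"`` a ``trial_key`` array (one group label per row) is
    required; whole groups are assigned to one side and the train size is
    then as close to the target as group granularity allows.
    """
    if n_total < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(spec.seed)
    n_train = int(round(spec.train_fraction * n_total))
    if spec.unit == "window-row":
        perm = rng.permutation(n_total)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])
    if trial_key is None:
        raise ValueError("trial-unit splitting requires trial_key")
    trial_key = np.asarray(trial_key)
    groups = np.unique(trial_key)
    perm = rng.permutation(groups)
    train_mask = np.zeros(n_total, dtype=bool)
    taken = 0
    for g in perm:
        members = trial_key == g
        if taken >= n_train:
            break
        train_mask |= members
        taken += int(members.sum())
    return np.flatnonzero(train_mask), np.flatnonzero(~train_mask)


def to_model_tensors(matrix: FeatureMatrix, label_spec: LabelSpec, allow_raw: bool = False):
    """(inputs, one-hot labels) ready for the 1-D CNNs.

    Inputs gain a trailing singleton channel axis: (n, width, 1).
    Raises on NaN inputs, and on an unstandardized matrix unless
    ``allow_raw`` explicitly waives the check.
    """
    if np.isnan(matrix.values).any():
        raise ValueError("feature matrix contains NaN")
    if not matrix.standardized and not allow_raw:
        raise ValueError(
            "feature matrix is not standardized; standardize first or pass allow_raw=True"
        )
    x = matrix.values[..., None]
    y = one_hot(binarize_rating(matrix.rating(label_spec.target)))
    return x, y
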