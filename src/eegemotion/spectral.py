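"""Sliding-window FFT band-power feature extraction.

Each EEG channel is cut into fixed-length windows advanced by a fixed
step (16 samples).  Every window is transformed with a one-sided DFT and
the magnitudes falling inside each of five frequency bands (theta, alpha,
low beta, high beta, gamma) are summed, giving one feature per
(channel, band) pair — 70 features for the default 14 channels x 5 bands.

Windowing arithmetic
--------------------
A window starting at offset ``s`` is admitted iff ``s + W < L`` (strictly),
with starts at multiples of the step ``S``.  For the DEAP trial length
L = 8064 and S = 16 this yields 488 windows per trial at W = 256 and the
window counts for every other window size follow the same rule.

Band aggregation sums one-sided FFT *magnitudes* ``|X[k]|`` per band.
Half-open band edges [low, high) ensure adjacent bands never double-count
a frequency bin; the DC bin is excluded by construction since every band
edge is at or above 4 Hz.  No taper is applied before the FFT and no
detrending is performed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.preprocessing import StandardScaler

from .io import RATING_NAMES, Recording, ChannelMap, DEFAULT_CHANNEL_MAP

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "WindowPlan",
    "FeatureMatrix",
    "plan_windows",
    "band_bins",
    "band_power",
    "extract_features",
    "standardize",
    "DEFAULT_WINDOW",
    "DEFAULT_STEP",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 256
DEFAULT_STEP = 16


@dataclass(frozen=True)
class BandSpec:
    """Named frequency band with half-open edges [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: edges must satisfy 0 < low < high, "
                f"got [{self.low}, {self.high})"
            )


#: The five-band bank used throughout: theta, alpha, low beta, high beta,
#: gamma.  Consistent with DEAP's 4-45 Hz band-pass preprocessing.
DEFAULT_BANDS = (
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("low_beta", 12.0, 16.0),
    BandSpec("high_beta", 16.0, 25.0),
    BandSpec("gamma", 25.0, 45.0),
)


@dataclass(frozen=True)
class WindowPlan:
    """Start offsets of all admitted sliding windows over one trial."""

    window_size: int
    step: int
    trial_length: int
    starts: tuple

    @property
    def n_windows(self) -> int:
        return len(self.starts)


def plan_windows(trial_length: int, window_size: int, step: int) -> WindowPlan:
    """Enumerate sliding-window start offsets under the strict rule.

    A start ``s`` (a multiple of ``step``) is admitted iff
    ``s + window_size < trial_length``.  For (8064, 256, 16) this gives
    488 windows; for (8064, 1024, 16), 440.
    """
    if window_size < 1 or step < 1:
        raise ValueError(
            f"window_size and step must be >= 1, got W={window_size}, S={step}"
        )
    starts = tuple(range(0, max(trial_length - window_size, 0), step))
    return WindowPlan(window_size, step, trial_length, starts)


def band_bins(window_size: int, sample_rate: float, band: BandSpec) -> np.ndarray:
    """One-sided DFT bin indices k with low <= k * Fs / W < high.

    Only bins 0 .. floor(W/2) exist for a real signal.  The set may be
    empty when the window is too short to resolve the band.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    k = np.arange(window_size // 2 + 1)
    freqs = k * sample_rate / window_size
    return k[(freqs >= band.low) & (freqs < band.high)]


def band_power(window_signal, sample_rate: float, bands=DEFAULT_BANDS) -> np.ndarray:
    """Per-band sum of one-sided FFT magnitudes for one window.

    Empty bin sets contribute 0.  Raises ``ValueError`` on a non-1-D input.
    """
    x = np.asarray(window_signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"window_signal must be 1-D, got shape {x.shape}")
    mags = np.abs(np.fft.rfft(x))
    out = np.empty(len(bands))
    for i, band in enumerate(bands):
        bins = band_bins(len(x), sample_rate, band)
        out[i] = mags[bins].sum() if len(bins) else 0.0
    return out


@dataclass
class FeatureMatrix:
    """Windows x features table of band powers with per-window provenance.

    ``values`` has one row per window; columns are named
    ``<electrode>_<band>`` in channel-major order, optionally followed by
    appended rating-extension columns.  ``ratings`` carries the source
    trial's four self-assessment scores for every window, and
    ``provenance`` records (participant_id, trial, start offset).
    """

    values: np.ndarray
    feature_names: list
    ratings: np.ndarray                      # (n_windows, 4)
    trial_index: np.ndarray                  # (n_windows,)
    start_offset: np.ndarray                 # (n_windows,)
    participant_id: np.ndarray               # (n_windows,) of str
    standardized: bool = False
    extension: tuple = ()

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def rating(self, name: str) -> np.ndarray:
        return self.ratings[:, RATING_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: feature columns then the four rating columns."""
        df = pd.DataFrame(self.values, columns=self.feature_names)
        for i, rn in enumerate(RATING_NAMES):
            df[rn] = self.ratings[:, i]
        df["trial"] = self.trial_index
        df["start"] = self.start_offset
        df["participant"] = self.participant_id
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta_cols = list(RATING_NAMES) + ["trial", "start", "participant"]
        feat_cols = [c for c in df.columns if c not in meta_cols]
        return cls(
            values=df[feat_cols].to_numpy(dtype=np.float64),
            feature_names=feat_cols,
            ratings=df[list(RATING_NAMES)].to_numpy(dtype=np.float64),
            trial_index=df["trial"].to_numpy(dtype=np.int64),
            start_offset=df["start"].to_numpy(dtype=np.int64),
            participant_id=df["participant"].to_numpy(dtype=str),
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def concat(cls, matrices) -> "FeatureMatrix":
        matrices = list(matrices)
        names = matrices[0].feature_names
        for m in matrices[1:]:
            if m.feature_names != names:
                raise ValueError("cannot concatenate: feature names differ")
        return cls(
            values=np.concatenate([m.values for m in matrices]),
            feature_names=list(names),
            ratings=np.concatenate([m.ratings for m in matrices]),
            trial_index=np.concatenate([m.trial_index for m in matrices]),
            start_offset=np.concatenate([m.start_offset for m in matrices]),
            participant_id=np.concatenate([m.participant_id for m in matrices]),
            standardized=all(m.standardized for m in matrices),
            extension=matrices[0].extension,
        )


def extract_features(
    rec: Recording,
    channels=None,
    bands=DEFAULT_BANDS,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    channel_map: ChannelMap = DEFAULT_CHANNEL_MAP,
) -> FeatureMatrix:
    """Sliding-window band-power features for one recording.

    Parameters
    ----------
    rec : Recording
    channels : sequence of electrode names, optional
        Defaults to the 14 study electrodes of the channel map.
    bands : sequence of BandSpec
    window_size, step : int
        Sliding-window length and hop in samples.

    Returns
    -------
    FeatureMatrix with rows ordered trial-major then start-ascending and
    columns ``<electrode>_<band>`` in channel-major order.
    """
    names = list(channels) if channels is not None else list(channel_map.selected)
    idx = [channel_map.index(n) for n in names]
    bad = [i for i in idx if i >= rec.n_channels]
    if bad:
        raise ValueError(f"channel indices {bad} out of range for recording")

    plan = plan_windows(rec.n_samples, window_size, step)
    n_ch, n_b, n_w = len(idx), len(bands), plan.n_windows
    masks = np.zeros((n_b, window_size // 2 + 1), dtype=bool)
    for b, band in enumerate(bands):
        masks[b, band_bins(window_size, rec.sample_rate, band)] = True

    feature_names = [f"{ch}_{band.name}" for ch in names for band in bands]
    values = np.empty((rec.n_trials * n_w, n_ch * n_b))
    starts = np.asarray(plan.starts)
    for t in range(rec.n_trials):
        sig = rec.data[t, idx, :]                      # (n_ch, L)
        if n_w == 0:
            continue
        wins = sliding_window_view(sig, window_size, axis=1)[:, starts, :]
        mags = np.abs(np.fft.rfft(wins, axis=-1))      # (n_ch, n_w, W//2+1)
        bp = mags @ masks.T                            # (n_ch, n_w, n_b)
        values[t * n_w:(t + 1) * n_w] = bp.transpose(1, 0, 2).reshape(n_w, -1)

    return FeatureMatrix(
        values=values,
        feature_names=feature_names,
        ratings=np.repeat(rec.ratings, n_w, axis=0),
        trial_index=np.repeat(np.arange(rec.n_trials), n_w),
        start_offset=np.tile(starts, rec.n_trials).astype(np.int64)
        if n_w else np.empty(0, dtype=np.int64),
        participant_id=np.repeat(np.asarray([rec.participant_id]), rec.n_trials * n_w),
    )


def standardize(matrix: FeatureMatrix, scaler: StandardScaler | None = None):
    """Z-score every feature column; returns (new matrix, fitted scaler).

    When ``scaler`` is given its stored statistics are applied instead of
    refitting (use for transforming held-out data with train statistics).
    Zero-variance columns keep a scale of 1 and a warning is logged.
    """
    if scaler is None:
        if matrix.n_windows < 2:
            raise ValueError("need at least 2 windows to fit column statistics")
        scaler = StandardScaler()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaler.fit(matrix.values)
        constant = np.flatnonzero(np.isclose(scaler.var_, 0.0))
        if constant.size:
            logger.warning(
                "zero-variance feature columns %s: substituting scale 1",
                [matrix.feature_names[i] for i in constant],
            )
    transformed = scaler.transform(matrix.values)
    return replace(matrix, values=transformed, standardized=True), scaler
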