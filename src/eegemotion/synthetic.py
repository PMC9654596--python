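"""Synthetic DEAP-shaped EEG with a planted band-power <-> rating dependence.

Real DEAP downloads are registration-gated, so every downstream stage is
exercised on generated recordings that reproduce the dataset's geometry
exactly: 40 trials x 40 channels x 8064 samples at 128 Hz per participant,
with four continuous self-assessment ratings per trial on the 1-9 scale.

Each channel is a sum of band-limited noise components, one per frequency
band, plus a broadband noise floor.  A band component's amplitude is a
linear function of one of the trial's ratings, so the spectral content of
a trial encodes its ratings — the controllable stand-in for whatever
neural correlate the real data carries.  Band-limited noise (white noise
spectrally confined to the band) rather than pure tones gives the FFT
features realistic within-band spread.

Ratings are drawn once per trial and held constant across all of its
windows, mirroring DEAP's per-video labels.  All randomness derives from
a single seed through per-(participant, trial) substreams, so partial
regeneration is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Recording, RATING_NAMES
from .spectral import BandSpec, DEFAULT_BANDS

__all__ = [
    "BandGain",
    "SynthConfig",
    "generate_participant",
    "generate_dataset",
    "separable_config",
]


@dataclass(frozen=True)
class BandGain:
    """Linear rating -> amplitude law for one band component.

    amplitude = base + slope * (rating - 5) / 4, floored at 0, where
    ``rating`` is the trial's value of ``drives`` (one of valence,
    arousal, dominance, liking).  With slope 0 the band is rating-blind.
    """

    base: float = 1.0
    slope: float = 0.0
    drives: str = "valence"

    def amplitude(self, ratings: np.ndarray) -> float:
        r = ratings[RATING_NAMES.index(self.drives)]
        return max(self.base + self.slope * (r - 5.0) / 4.0, 0.0)


def _default_band_gains() -> dict:
    # Alpha power tracks valence and high-beta tracks arousal, the two
    # target labels; remaining bands are rating-blind context.
    return {
        "theta": BandGain(1.0, 0.0),
        "alpha": BandGain(1.0, 0.8, "valence"),
        "low_beta": BandGain(1.0, 0.0),
        "high_beta": BandGain(1.0, 0.6, "arousal"),
        "gamma": BandGain(0.8, 0.0),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the synthetic generator.

    ``rating_law`` chooses how the four per-trial ratings are drawn:

    ``"uniform"``
        Independent continuous uniform on [1, 9] — the default, matching
        the nominal spread of self-assessment scores.
    ``"two_cluster"``
        The target rating (valence) takes the two cluster values in a
        balanced design — half the trials each, in seeded random order —
        while the others stay uniform: two well-separated affective
        states with exactly balanced classes, used for separability
        studies.
    """

    n_trials: int = 40
    n_channels: int = 40
    n_samples: int = 8064
    sample_rate: float = 128.0
    band_gains: dict = field(default_factory=_default_band_gains)
    noise_floor: float = 0.5
    rating_law: str = "uniform"
    cluster_ratings: tuple = (2.0, 8.0)
    cluster_target: str = "valence"
    bands: tuple = DEFAULT_BANDS
    seed: int = 0

    def __post_init__(self):
        nyquist = self.sample_rate / 2.0
        for band in self.bands:
            if band.high > nyquist:
                raise ValueError(
                    f"band {band.name!r} upper edge {band.high} Hz exceeds "
                    f"the Nyquist frequency {nyquist} Hz"
                )
        if self.rating_law not in ("uniform", "two_cluster"):
            raise ValueError(f"unknown rating_law {self.rating_law!r}")


def _draw_ratings(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    ratings = rng.uniform(1.0, 9.0, size=(cfg.n_trials, 4))
    if cfg.rating_law == "two_cluster":
        col = RATING_NAMES.index(cfg.cluster_target)
        lo, hi = cfg.cluster_ratings
        half = cfg.n_trials // 2
        assigned = np.r_[np.full(half, lo), np.full(cfg.n_trials - half, hi)]
        ratings[:, col] = rng.permutation(assigned)
    return ratings


def _band_noise(rng: np.random.Generator, shape, fs: float, band: BandSpec) -> np.ndarray:
    """Unit-RMS white noise spectrally confined to [low, high); rows independent."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / fs)
    spec[..., (freqs < band.low) | (freqs >= band.high)] = 0.0
    shaped = np.fft.irfft(spec, shape[-1], axis=-1)
    rms = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    return shaped / np.where(rms > 0, rms, 1.0)


def generate_participant(cfg: SynthConfig, participant: int = 0) -> Recording:
    """Generate one DEAP-shaped participant recording.

    Fully reproducible: the same (config, participant) pair always yields
    the same arrays.  Distinct participants under one seed use disjoint
    random substreams.
    """
    rating_rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(participant, 2**16))
    )
    ratings = _draw_ratings(cfg, rating_rng)

    shape = (cfg.n_channels, cfg.n_samples)
    data = np.empty((cfg.n_trials, cfg.n_channels, cfg.n_samples))
    for t in range(cfg.n_trials):
        amps = [
            (band, cfg.band_gains.get(band.name, BandGain()).amplitude(ratings[t]))
            for band in cfg.bands
        ]
        trial_rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=(participant, t))
        )
        sig = cfg.noise_floor * trial_rng.standard_normal(shape)
        for band, amp in amps:
            if amp > 0:
                sig = sig + amp * _band_noise(trial_rng, shape, cfg.sample_rate, band)
        data[t] = sig

    return Recording(
        data=data,
        ratings=ratings,
        sample_rate=cfg.sample_rate,
        participant_id=f"synth{participant:02d}",
        meta={"seed": cfg.seed, "config": _config_dict(cfg), "participant": participant},
    )


def generate_dataset(cfg: SynthConfig, n_participants: int) -> list:
    """Generate a list of participant recordings under one config."""
    return [generate_participant(cfg, p) for p in range(n_participants)]


def _config_dict(cfg: SynthConfig) -> dict:
    return {
        "n_trials": cfg.n_trials,
        "n_channels": cfg.n_channels,
        "n_samples": cfg.n_samples,
        "sample_rate": cfg.sample_rate,
        "noise_floor": cfg.noise_floor,
        "rating_law": cfg.rating_law,
        "cluster_ratings": list(cfg.cluster_ratings),
        "cluster_target": cfg.cluster_target,
        "seed": cfg.seed,
        "band_gains": {
            name: {"base": g.base, "slope": g.slope, "drives": g.drives}
            for name, g in cfg.band_gains.items()
        },
    }


def separable_config(seed: int = 0, slope: float = 2.4, **kw) -> SynthConfig:
    """Two-cluster study condition with strong, distinct band gains.

    Valence clusters at {2, 8} drive the alpha amplitude from near zero
    (low cluster) to roughly three times baseline (high cluster), a
    separation a spectral classifier should resolve essentially perfectly.
    """
    gains = _default_band_gains()
    gains["alpha"] = BandGain(1.8, slope, "valence")
    return SynthConfig(rating_law="two_cluster", band_gains=gains, seed=seed, **kw)
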