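"""Reading and writing DEAP-style preprocessed EEG recordings.

The DEAP distribution stores one file per participant holding a
``data`` array of shape (40 trials, 40 channels, 8064 samples) sampled at
128 Hz and a ``labels`` array of shape (40, 4) with the self-assessment
ratings (valence, arousal, dominance, liking), each on a continuous 1-9
scale.  Two on-disk dialects are supported:

``pickled-dict``
    The layout of the original preprocessed distribution: a pickle of a
    dictionary with ``data`` and ``labels`` keys (files named ``s01.dat``
    and so on).

``hdf5``
    An open, self-describing container used for synthetic fixtures, with
    ``data`` and ``labels`` datasets plus generator metadata stored as
    attributes (seed, configuration JSON).
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "Recording",
    "ChannelMap",
    "GENEVA_32",
    "STUDY_14",
    "DEFAULT_CHANNEL_MAP",
    "FormatError",
    "ValidationError",
    "load_recording",
    "save_recording",
    "resolve_channels",
]

#: Electrode names of the 32 EEG channels in the order used by the
#: preprocessed DEAP files ("Geneva order").  Channels 32-39 of the data
#: array are peripheral physiological channels and carry no electrode name.
GENEVA_32 = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

#: The 14 electrodes of the Emotiv EPOC+ headset used for feature
#: extraction, given by name (order is the feature-column order).
STUDY_14 = (
    "Fp1", "AF3", "F3", "F7", "FC1", "P3", "PO3",
    "Fp2", "Fz", "F4", "F8", "C4", "P4", "PO4",
)

RATING_NAMES = ("valence", "arousal", "dominance", "liking")

DEAP_N_TRIALS = 40
DEAP_N_CHANNELS = 40
DEAP_N_SAMPLES = 8064
DEAP_SAMPLE_RATE = 128.0


class FormatError(ValueError):
    """A file does not contain the arrays the dialect promises."""


class ValidationError(ValueError):
    """Array contents violate the documented DEAP invariants."""


@dataclass(frozen=True)
class ChannelMap:
    """Bijective electrode-name -> channel-index map over the EEG channels.

    Indices are 0-based internally; all public interfaces speak electrode
    names.  ``selected`` is the ordered subset used for feature extraction.
    """

    names: tuple = GENEVA_32
    selected: tuple = STUDY_14

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValidationError("channel names must be unique")
        missing = [n for n in self.selected if n not in self.names]
        if missing:
            raise ValidationError(f"selected electrodes not in map: {missing}")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown electrode {name!r}; valid names: {', '.join(self.names)}"
            ) from None

    @property
    def selected_indices(self) -> tuple:
        return tuple(self.index(n) for n in self.selected)


DEFAULT_CHANNEL_MAP = ChannelMap()


def resolve_channels(names, channel_map: ChannelMap = DEFAULT_CHANNEL_MAP):
    """Resolve electrode names to 0-based channel indices, order preserved.

    Raises ``KeyError`` listing the valid names if a name is unknown.
    """
    return [channel_map.index(n) for n in names]


@dataclass
class Recording:
    """One participant's trials x channels x samples tensor plus ratings.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Preprocessed EEG amplitude (arbitrary units after DEAP averaging).
    ratings : ndarray, shape (n_trials, 4)
        Self-assessment ratings in the order valence, arousal, dominance,
        liking; each value lies in [1, 9].
    sample_rate : float
        Sampling rate in Hz (128 for DEAP-conformant recordings).
    participant_id : str
        Identifier, e.g. ``"s01"``.
    meta : dict
        Free-form provenance (synthetic generator seed and config, etc.).
    """

    data: np.ndarray
    ratings: np.ndarray
    sample_rate: float = DEAP_SAMPLE_RATE
    participant_id: str = "s00"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.ratings = np.asarray(self.ratings, dtype=np.float64)
        validate_recording(self)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def is_deap_shaped(self) -> bool:
        return (
            self.data.shape == (DEAP_N_TRIALS, DEAP_N_CHANNELS, DEAP_N_SAMPLES)
            and self.sample_rate == DEAP_SAMPLE_RATE
        )


def validate_recording(rec: Recording) -> None:
    if rec.data.ndim != 3:
        raise ValidationError(
            f"data must be 3-D (trials, channels, samples); got shape {rec.data.shape}"
        )
    if rec.ratings.ndim != 2 or rec.ratings.shape[1] != 4:
        raise ValidationError(
            f"ratings must have shape (n_trials, 4); got {rec.ratings.shape}"
        )
    if rec.ratings.shape[0] != rec.data.shape[0]:
        raise ValidationError(
            f"trial count mismatch: data has {rec.data.shape[0]} trials, "
            f"ratings {rec.ratings.shape[0]}"
        )
    if not np.all((rec.ratings >= 1.0) & (rec.ratings <= 9.0)):
        bad = rec.ratings[(rec.ratings < 1.0) | (rec.ratings > 9.0)]
        raise ValidationError(
            f"ratings outside the documented [1, 9] scale: {bad[:5]}"
        )
    if rec.sample_rate <= 0:
        raise ValidationError("sample_rate must be positive")


def _infer_dialect(path: Path) -> str:
    if path.suffix in (".h5", ".hdf5"):
        return "hdf5"
    return "pickled-dict"


def load_recording(path, dialect: str | None = None) -> Recording:
    """Load a participant recording from disk.

    Parameters
    ----------
    path : str or Path
    dialect : {"pickled-dict", "hdf5"}, optional
        Inferred from the file extension when omitted (``.h5``/``.hdf5``
        mean hdf5, everything else the pickled dictionary).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "pickled-dict":
        with open(path, "rb") as fh:
            obj = pickle.load(fh, encoding="latin1")
        if not isinstance(obj, dict) or "data" not in obj or "labels" not in obj:
            raise FormatError(
                f"{path}: pickled-dict dialect requires a dict with "
                "'data' and 'labels' keys"
            )
        return Recording(
            data=obj["data"],
            ratings=obj["labels"],
            sample_rate=float(obj.get("sample_rate", DEAP_SAMPLE_RATE)),
            participant_id=str(obj.get("participant_id", path.stem)),
            meta={k: v for k, v in obj.items() if k not in ("data", "labels")},
        )
    if dialect == "hdf5":
        with h5py.File(path, "r") as fh:
            if "data" not in fh or "labels" not in fh:
                raise FormatError(
                    f"{path}: hdf5 dialect requires 'data' and 'labels' datasets"
                )
            meta = {}
            if "config" in fh.attrs:
                meta["config"] = json.loads(fh.attrs["config"])
            if "seed" in fh.attrs:
                meta["seed"] = int(fh.attrs["seed"])
            return Recording(
                data=fh["data"][()],
                ratings=fh["labels"][()],
                sample_rate=float(fh.attrs.get("sample_rate", DEAP_SAMPLE_RATE)),
                participant_id=str(fh.attrs.get("participant_id", path.stem)),
                meta=meta,
            )
    raise ValueError(f"unknown dialect {dialect!r}")


def save_recording(rec: Recording, path, dialect: str | None = None) -> Path:
    """Write a recording to disk; inverse of :func:`load_recording`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dialect = dialect or _infer_dialect(path)
    if dialect == "pickled-dict":
        obj = {
            "data": rec.data,
            "labels": rec.ratings,
            "sample_rate": rec.sample_rate,
            "participant_id": rec.participant_id,
        }
        with open(path, "wb") as fh:
            pickle.dump(obj, fh)
    elif dialect == "hdf5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=rec.data)
            fh.create_dataset("labels", data=rec.ratings)
            fh.attrs["sample_rate"] = rec.sample_rate
            fh.attrs["participant_id"] = rec.participant_id
            if "seed" in rec.meta:
                fh.attrs["seed"] = int(rec.meta["seed"])
            if "config" in rec.meta:
                fh.attrs["config"] = json.dumps(rec.meta["config"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path
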