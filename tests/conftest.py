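"""Shared fixtures: synthetic recordings at several problem sizes.

Expensive fixtures (full DEAP geometry, multi-participant separable
datasets) are session-scoped so the cost is paid once.
"""

import numpy as np
import pytest

from eegemotion.synthetic import SynthConfig, generate_dataset, generate_participant, separable_config


@pytest.fixture(scope="session")
def tiny_recording():
    """Small separable recording for fast pipeline tests (8 trials, ~9 s)."""
    cfg = separable_config(seed=7, n_trials=8, n_samples=1200)
    return generate_participant(cfg, 0)


@pytest.fixture(scope="session")
def deap_recording():
    """One participant at full DEAP geometry: 40 x 40 x 8064 at 128 Hz."""
    return generate_participant(SynthConfig(seed=11), 0)


@pytest.fixture(scope="session")
def separable_recordings():
    """Four participants with the two-cluster valence law and strong gains."""
    return generate_dataset(separable_config(seed=1), 4)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
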