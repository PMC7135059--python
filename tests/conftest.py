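import numpy as np
import pytest

from pupilpipe.synthetic import SimConfig, visual_study_config


@pytest.fixture(scope="session")
def default_visual() -> SimConfig:
    return visual_study_config(seed=11)


@pytest.fixture(scope="session")
def tiny_visual() -> SimConfig:
    """Shrunk session (6 stimuli, 10-trial detection blocks) for fast
    end-to-end tests; same structural invariants as the full design."""
    return visual_study_config(
        seed=11, n_participants=2, n_stimuli=6, detection_trials=10
    )


@pytest.fixture()
def clean_visual() -> SimConfig:
    """Noise-free, blink-free single-participant visual config."""
    return visual_study_config(
        seed=5,
        n_participants=1,
        noise_sd=0.0,
        blink_rate=0.0,
        participant_sd=0.0,
        participant_gain_sd=0.0,
        trial_gain_sd=0.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
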