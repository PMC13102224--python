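import numpy as np
import pytest

from rmetnet import SynthConfig, generate_subjects
from rmetnet.network import preset


@pytest.fixture(scope="session")
def small_trial_set():
    """4 subjects x 2 classes x 10 trials/class of 6-channel 1-s trials."""
    return generate_subjects(
        SynthConfig(n_subjects=4, trials_per_class=10, n_channels=6, n_samples=250, seed=7)
    )


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """A very small architecture for fast training-path tests."""
    import dataclasses

    return dataclasses.replace(
        preset("synthetic-small"), F1=4, F2=8, tslanet_layers=1, hidden_width=32
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, c=4, scale=1.0):
    a = rng.normal(size=(c, c))
    return a @ a.T * scale + np.eye(c) * 0.5
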