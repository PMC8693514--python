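import numpy as np
import pytest

from macgrip.model import build_default_model
from macgrip.synth import SynthConfig, generate_trial


@pytest.fixture(scope="session")
def model():
    return build_default_model()


@pytest.fixture(scope="session")
def short_config():
    """A short synthetic trial (1 s) for pipeline tests."""
    return SynthConfig(
        seed=42,
        duration_s=1.0,
        grip_onset_s=0.2,
        peak_s=0.5,
        release_s=0.8,
        marker_noise_mm=0.0,
    )


@pytest.fixture(scope="session")
def short_trial(short_config, model):
    """Noise-free short trial with ground truth (solved once per session)."""
    return generate_trial(short_config, model=model)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
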