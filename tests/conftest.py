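import numpy as np
import pytest

from hmdpulse.synth import SceneConfig, generate_clip


@pytest.fixture(scope="session")
def small_clip():
    """2-second 30 FPS clip at reduced resolution, static face, no noise."""
    return generate_clip(SceneConfig(width=320, height=240, fps=30.0, duration=2.0,
                                     heart_rate=72.0, pulse_amplitude=10.0, seed=1))


@pytest.fixture(scope="session")
def long_clip():
    """60-second clip for spectral checks (tiny frames to keep it fast)."""
    return generate_clip(SceneConfig(width=96, height=72, fps=30.0, duration=60.0,
                                     heart_rate=72.0, pulse_amplitude=10.0, seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
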