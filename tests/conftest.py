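import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_samples():
    """Small pool of clean low-resolution tray scenes (session-cached)."""
    from shrimpdet.synthgen import easy_params, generate_sample
    p = easy_params(image_size=160)
    return [generate_sample(p, np.random.default_rng([9, i])) for i in range(8)]


@pytest.fixture(scope="session")
def default_samples():
    """Scenes at the default (realistic) generator settings."""
    from shrimpdet.synthgen import SceneParams, generate_sample
    p = SceneParams(image_size=256)
    return [generate_sample(p, np.random.default_rng([11, i])) for i in range(12)]
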