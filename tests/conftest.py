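import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_texture_set():
    """4-class grating tile set shared by dataset/backbone tests."""
    from histospect.synthetic import TextureDatasetSpec, generate_texture_dataset

    spec = TextureDatasetSpec(n_classes=4, per_class=6, tile_size=64, seed=7)
    return generate_texture_dataset(spec)
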