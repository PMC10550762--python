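import numpy as np
import pytest
from hypothesis import settings

from hescrub.synthetic import SyntheticParams, generate_sample

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def clean_sample():
    """Clean field: 12 well-separated round nuclei, flat background, no noise."""
    return generate_sample(SyntheticParams(
        image_size=(384, 384), n_nuclei=12, radius_range=(14.0, 20.0),
        background_preset="flat", noise_amplitude=0.0, seed=3))


@pytest.fixture(scope="session")
def fibrous_sample():
    """Noisy field: nuclei over dense fibrous stroma."""
    return generate_sample(SyntheticParams(
        image_size=(512, 512), n_nuclei=25, radius_range=(12.0, 20.0),
        background_preset="fibrous_stroma", seed=11))
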