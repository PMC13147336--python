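import numpy as np
import pytest

from hemebundle.synthetic import SandwichBlueprint, assemble_sandwich


@pytest.fixture(scope="session")
def clean_sandwich():
    """Jitter-free 2-model sandwich: descriptors must equal the blueprint."""
    bp = SandwichBlueprint(
        target_interhelical_angle=64.0,
        target_theta_his=20.0,
        metal_offset=7.0,
        jitter_sd=0.0,
        n_models=2,
        seed=0,
    )
    return assemble_sandwich(bp)


@pytest.fixture(scope="session")
def jittered_sandwich():
    """20-model ensemble with 0.3 Å per-atom jitter (the stated noise level)."""
    bp = SandwichBlueprint(
        target_interhelical_angle=64.0,
        target_theta_his=20.0,
        metal_offset=7.0,
        jitter_sd=0.3,
        n_models=20,
        seed=1,
    )
    return assemble_sandwich(bp)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
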