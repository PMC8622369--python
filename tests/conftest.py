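import numpy as np
import pytest

from caeprep import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_spec():
    """Small 3-class noisy dataset spec used across modules."""
    return SyntheticSpec(
        n_classes=3, samples_per_class=8, height=16, width=16,
        signal_amplitude=0.5, noise_model="gaussian", noise_sigma=0.15,
        clutter_amplitude=0.05, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_ds(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
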