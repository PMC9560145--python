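import numpy as np
import pytest

from cocoonct.phantom import PhantomSpec, generate_phantom


def clean_phantom_spec(seed: int = 7, shape=(96, 96, 96), n_cocoons: int = 30,
                       parasitoid_fraction: float = 0.2) -> PhantomSpec:
    """Noise-free, blur-free phantom with well-separated cocoons."""
    return PhantomSpec(volume_shape=shape, n_cocoons=n_cocoons,
                       parasitoid_fraction=parasitoid_fraction,
                       semi_axis_range=((5.0, 8.0), (3.5, 5.0), (3.5, 5.0)),
                       noise_sd=0.0, blur_sigma=0.0, seed=seed)


@pytest.fixture(scope="session")
def clean_phantom():
    """One 96^3 noise-free phantom shared across tests: (hu, labels, instances, truth)."""
    return generate_phantom(clean_phantom_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
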