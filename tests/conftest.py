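import numpy as np
import pytest

from slowosc import (
    CalciumSimParams,
    PlaqueSimParams,
    VSDSimParams,
    generate_calcium_stack,
    generate_plaque_volume,
    generate_vsd_movie,
)


@pytest.fixture(scope="session")
def clean_vsd_movie():
    """Noiseless, fully synchronized 50-s movie at the endogenous 0.6 Hz."""
    movie, truth = generate_vsd_movie(VSDSimParams(noise_sd=0.0, seed=0))
    return movie, truth


@pytest.fixture(scope="session")
def calcium_stack_noiseless():
    params = CalciumSimParams(n_neurites=20, photon_noise_scale=0.0, seed=1)
    stack, truth = generate_calcium_stack(params)
    return stack, truth, params


@pytest.fixture(scope="session")
def plaque_volume_ten():
    """A seeded volume whose ground truth holds exactly 10 separated plaques."""
    params = PlaqueSimParams(volume_shape=(80, 256, 256), density_per_mm3=95.0, seed=6)
    volume, truth = generate_plaque_volume(params)
    assert truth.count == 10
    return volume, truth, params
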