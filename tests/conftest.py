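import numpy as np
import pytest

from tissuedyn import SyntheticImageParams, generate_tissue_image


@pytest.fixture(scope="session")
def small_params():
    """A small, fast tissue image: 6 crypts x 12 cells, default noise."""
    return SyntheticImageParams(
        image_height=300, image_width=420, n_crypts=6, cells_per_crypt=12, seed=11
    )


@pytest.fixture(scope="session")
def small_image(small_params):
    return generate_tissue_image(small_params)


@pytest.fixture(scope="session")
def noisefree_params(small_params):
    import dataclasses

    return dataclasses.replace(small_params, noise_model="none")


@pytest.fixture(scope="session")
def noisefree_image(noisefree_params):
    return generate_tissue_image(noisefree_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
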