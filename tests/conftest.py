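import numpy as np
import pytest

from turflag.grid import KernelSpec, make_grid
from turflag.synthetic import (
    SyntheticDesign,
    generate_turf_series,
    sample_taxon_params,
)


@pytest.fixture(scope="session")
def grid():
    return make_grid(1.0, 0.05, 0.10)


@pytest.fixture(scope="session")
def kernel():
    return KernelSpec()


@pytest.fixture(scope="session")
def default_params():
    design = SyntheticDesign()
    return sample_taxon_params(design, np.random.default_rng(0))


@pytest.fixture(scope="session")
def clean_dataset(default_params):
    """Synthetic study with no observation noise (tracking oracle)."""
    design = SyntheticDesign(displacement_rate=0.0)
    return generate_turf_series(design, default_params, np.random.default_rng(1))


@pytest.fixture(scope="session")
def noisy_dataset(default_params):
    """Synthetic study with 10% one-quadrant displacement noise."""
    design = SyntheticDesign(displacement_rate=0.10)
    return generate_turf_series(design, default_params, np.random.default_rng(1))
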