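import numpy as np
import pytest

from stormclust import FieldGeometry, SyntheticConfig, generate_monomer_field


@pytest.fixture
def square_10um():
    return FieldGeometry.square_um(10, "toroidal")


@pytest.fixture
def square_3um():
    return FieldGeometry.square_um(3, "toroidal")


@pytest.fixture(scope="session")
def sparse_monomer_field():
    """A well-separated monomer field (5 molecules/um^2) with ground truth."""
    geom = FieldGeometry.square_um(10, "toroidal")
    cfg = SyntheticConfig(geometry=geom, molecule_density=5, loc_sigma=10.0, seed=7)
    return generate_monomer_field(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
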