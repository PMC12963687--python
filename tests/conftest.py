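import numpy as np
import pytest

from tlspatial.data import SpatialDataset
from tlspatial.simulate import lattice_coords


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def square_coords():
    """6 x 6 square lattice at 100 um pitch."""
    return lattice_coords("square", 6, 6, 100.0)


@pytest.fixture
def small_dataset(rng, square_coords):
    """Random 20-gene x 36-spot count dataset on the square lattice."""
    genes = np.array([f"G{i:02d}" for i in range(20)])
    counts = rng.poisson(5, size=(20, 36))
    spot_ids = np.array([f"S{i:02d}" for i in range(36)])
    return SpatialDataset(
        spot_ids=spot_ids,
        coords=square_coords,
        genes=genes,
        matrix=counts,
        units="counts",
    )
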