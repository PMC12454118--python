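import numpy as np
import pytest

from biopressure.grid import GridSpec, Layer
from biopressure.pressure import CropData, RichnessLayer
from biopressure.synthetic import WorldConfig, generate_world


@pytest.fixture
def small_spec():
    return GridSpec(n_rows=6, n_cols=8, cell_size=7.5, origin_lon=-30.0, origin_lat=45.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_layer(spec, values, units="", mask=None):
    values = np.broadcast_to(np.asarray(values, float), spec.shape).copy()
    return Layer(spec, values, mask, units)


@pytest.fixture
def small_crop(small_spec, rng):
    ha = make_layer(small_spec, rng.uniform(0, 100, small_spec.shape), "ha")
    yld = make_layer(small_spec, rng.uniform(0.5, 10, small_spec.shape), "t ha-1")
    return CropData("apples", ha, yld, water_pct=84.0)


@pytest.fixture
def small_richness(small_spec, rng):
    sr = make_layer(
        small_spec, rng.integers(0, 300, small_spec.shape).astype(float), "species"
    )
    return RichnessLayer(sr)


@pytest.fixture(scope="session")
def default_world():
    """The standard seeded study system: 24x48 grid, 3 countries, 4 crops."""
    return generate_world(WorldConfig(seed=7))
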