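import numpy as np
import pytest

from ecoserv.grids import LandUseRaster
from ecoserv.params import (load_carbon_density, load_esv_coefficients,
                            load_landuse_attributes, load_sensitivity,
                            load_threats)
from ecoserv.synthetic import LandscapeSpec, generate_landuse


@pytest.fixture(scope="session")
def carbon_table():
    return load_carbon_density()


@pytest.fixture(scope="session")
def landuse_attrs():
    return load_landuse_attributes()


@pytest.fixture(scope="session")
def threats():
    return load_threats()


@pytest.fixture(scope="session")
def sensitivity():
    return load_sensitivity()


@pytest.fixture(scope="session")
def esv_coeffs():
    return load_esv_coefficients()


@pytest.fixture(scope="session")
def small_spec():
    return LandscapeSpec(grid_rows=50, grid_cols=50, seed=7)


@pytest.fixture(scope="session")
def small_landuse(small_spec):
    return generate_landuse(small_spec)


def toy_raster(codes, cell_size_km=1.0, nodata=-1, year=""):
    return LandUseRaster(np.asarray(codes, dtype=np.int64),
                         cell_size_km=cell_size_km, nodata=nodata, year=year)
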