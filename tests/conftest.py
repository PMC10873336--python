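import numpy as np
import pytest

from plantwin import (
    ClimateCube,
    GridGeometry,
    LandClass,
    LandMask,
    NoiseSpec,
    SyntheticSpec,
    Variable,
)


@pytest.fixture
def geom4() -> GridGeometry:
    """4x4 grid over a 2-degree square, half-degree cells."""
    return GridGeometry(
        n_rows=4, n_cols=4, lat_bounds=(-2.0, 0.0), lon_bounds=(30.0, 32.0), cell_size=0.5
    )


def make_cube(geom, variable, months, fill):
    """Cube with one constant field per month; ``months`` is [(y, m), ...]."""
    values = np.stack([np.full(geom.shape, v, dtype=float) for v in fill])
    return ClimateCube(geometry=geom, variable=variable, time_axis=tuple(months), values=values)


@pytest.fixture
def rain_year(geom4) -> ClimateCube:
    """One calendar year of rainfall, value = 10*month mm everywhere."""
    months = [(2001, m) for m in range(1, 13)]
    return make_cube(geom4, Variable.RAINFALL, months, [10.0 * m for m in range(1, 13)])


@pytest.fixture
def all_land(geom4) -> LandMask:
    return LandMask(geometry=geom4, classes=np.full(geom4.shape, int(LandClass.LAND)))


@pytest.fixture
def quiet_spec() -> SyntheticSpec:
    """Small noise-free bimodal synthetic region for exact structural checks."""
    return SyntheticSpec(n_rows=8, n_cols=8, years=(2000, 2002), noise_sd=NoiseSpec.zero(), seed=11)
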