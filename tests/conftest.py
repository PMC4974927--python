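import numpy as np
import pytest

from rangeshift.grids import ALL_VARS, ClimateStack, GridSpec, RangeMap
from rangeshift.synthetic import BASELINE, make_climate_stack


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(n_rows=24, n_cols=24, origin_lon=100.0, origin_lat=40.0,
                    cell_size=0.25)


@pytest.fixture(scope="session")
def small_stack(small_grid) -> ClimateStack:
    return make_climate_stack(small_grid, BASELINE, seed=7)


def range_map_from_cells(grid: GridSpec, cells, species_id="sp", scenario="s"):
    """Build a RangeMap with presence at the given (row, col) pairs."""
    presence = np.zeros(grid.shape, dtype=bool)
    for r, c in cells:
        presence[r, c] = True
    return RangeMap(species_id=species_id, scenario=scenario, grid=grid,
                    presence=presence)


@pytest.fixture(scope="session")
def tiny_grid() -> GridSpec:
    return GridSpec(n_rows=8, n_cols=8, origin_lon=0.0, origin_lat=4.0,
                    cell_size=0.5)
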