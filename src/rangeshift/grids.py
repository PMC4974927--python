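"""Raster grid containers: grids, climate stacks, suitability and range maps.

Conventions (fixed so results are bit-reproducible):

* geographic lon/lat degrees, north-up rasters;
* ``origin_lon`` is the west edge, ``origin_lat`` the north edge;
* cell centers sit half a cell in from the edges, so
  ``lon(col) = origin_lon + (col + 0.5) * cell_size`` and
  ``lat(row) = origin_lat - (row + 0.5) * cell_size`` — latitude decreases
  with row index;
* 0-based row/col indices; arrays are ``(n_rows, n_cols)`` float64/bool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, InvalidGridError, SchemaError

#: Climate predictor layers, in canonical band order. Elevation is carried in
#: the stack for altitude metrics but is never used as a predictor.
CLIMATE_VARS = (
    "annual_precip",       # mm
    "annual_mean_temp",    # degC
    "temp_seasonality",    # unitless (std-dev style index)
    "min_temp_coldest",    # degC
    "max_temp_warmest",    # degC
)
ELEVATION_VAR = "elevation"  # m
ALL_VARS = CLIMATE_VARS + (ELEVATION_VAR,)


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid, north-up, cell-center registered."""

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    cell_size: float
    elevation_model: str = "ridge_west"

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise InvalidGridError(
                f"grid must be at least 2x2, got {self.n_rows}x{self.n_cols}"
            )
        if not self.cell_size > 0:
            raise InvalidGridError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def lons(self) -> np.ndarray:
        """Cell-center longitudes, shape (n_cols,)."""
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lats(self) -> np.ndarray:
        """Cell-center latitudes, shape (n_rows,); decreasing (north-up)."""
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) center arrays, each shape (n_rows, n_cols)."""
        lon = np.broadcast_to(self.lons()[None, :], self.shape)
        lat = np.broadcast_to(self.lats()[:, None], self.shape)
        return lon.copy(), lat.copy()

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if outside."""
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row = int(np.floor((self.origin_lat - lat) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise InvalidGridError(f"point ({lon}, {lat}) outside grid")
        return row, col

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.isclose(self.origin_lon, other.origin_lon)
            and np.isclose(self.origin_lat, other.origin_lat)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def __hash__(self) -> int:  # frozen dataclass with custom __eq__
        return hash((self.n_rows, self.n_cols))


def _check_layer(grid: GridSpec, name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape != grid.shape:
        raise AlignmentError(
            f"layer '{name}' has shape {arr.shape}, grid is {grid.shape}"
        )
    return arr


@dataclass
class ClimateStack:
    """Aligned multi-variable climate rasters plus elevation for one scenario.

    ``layers`` maps variable name -> (n_rows, n_cols) array; exactly the five
    climate variables plus elevation must be present.  ``mask`` is True on
    valid (terrestrial/study-area) cells; masked cells are excluded from all
    statistics.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    mask: np.ndarray | None = None
    scenario: str = "baseline"

    def __post_init__(self) -> None:
        missing = [v for v in ALL_VARS if v not in self.layers]
        if missing:
            raise SchemaError(f"stack missing required layers: {missing}")
        extra = [v for v in self.layers if v not in ALL_VARS]
        if extra:
            raise SchemaError(f"stack has unknown layers: {extra}")
        self.layers = {k: _check_layer(self.grid, k, v) for k, v in self.layers.items()}
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise AlignmentError("mask shape does not match grid")

    @property
    def elevation(self) -> np.ndarray:
        return self.layers[ELEVATION_VAR]

    def climate_matrix(self) -> np.ndarray:
        """(n_cells, 5) matrix of climate variables in canonical order."""
        return np.column_stack([self.layers[v].ravel() for v in CLIMATE_VARS])

    def unmasked_indices(self) -> np.ndarray:
        """Flat indices of valid cells."""
        return np.flatnonzero(self.mask.ravel())


@dataclass
class SuitabilityMap:
    """Continuous per-cell habitat suitability in [0, 1] for one species x scenario."""

    species_id: str
    scenario: str
    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = _check_layer(self.grid, "suitability", self.values)
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        valid = self.values[self.mask]
        if valid.size and (np.nanmin(valid) < -1e-9 or np.nanmax(valid) > 1 + 1e-9):
            raise SchemaError("suitability values outside [0, 1]")


@dataclass
class RangeMap:
    """Binary presence/absence raster for one species x scenario."""

    species_id: str
    scenario: str
    grid: GridSpec
    presence: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.presence)
        if arr.shape != self.grid.shape:
            raise AlignmentError(
                f"presence shape {arr.shape} does not match grid {self.grid.shape}"
            )
        self.presence = arr.astype(bool)

    @property
    def area(self) -> int:
        """Occupied area in raw grid-cell counts."""
        return int(self.presence.sum())


def check_same_grid(*grids: GridSpec) -> GridSpec:
    """Require all grids equal; return the shared grid."""
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise AlignmentError("rasters are not on a shared grid")
    return first
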