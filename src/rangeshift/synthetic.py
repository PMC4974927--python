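"""Virtual climate and virtual species generation.

Synthetic stand-ins for bioclimatic raster stacks and occurrence records:
correlated climate surfaces with a north-south temperature gradient, an
elevation lapse term and smoothed random-field noise; future scenarios as
parametric warming/drying deltas on the baseline; and virtual species whose
suitability is a known product of Gaussian responses, so that the true range
response to a scenario is known by construction and downstream estimators can
be validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InfeasibleSampleError, SchemaError
from .grids import (
    ALL_VARS,
    CLIMATE_VARS,
    ClimateStack,
    GridSpec,
    SuitabilityMap,
)

# Temperature-layer names that receive the scenario warming delta.
TEMP_LAYERS = ("annual_mean_temp", "min_temp_coldest", "max_temp_warmest")

#: Environmental lapse rate used for the elevation term of temperature, degC/km.
LAPSE_RATE = 6.5
#: Latitudinal temperature gradient, degC per degree latitude.
LAT_GRADIENT = 0.8


@dataclass(frozen=True)
class ScenarioSpec:
    """A climate scenario as parametric deltas on the baseline.

    ``temp_delta`` (degC) is added to every temperature layer cell-wise,
    ``precip_factor`` multiplies annual precipitation, ``seasonality_delta``
    is added to temperature seasonality.  The baseline scenario has the
    identity deltas (0, 1, 0).
    """

    name: str
    period: str = "baseline"  # baseline | 2050s | 2070s
    pathway: str = "baseline"  # e.g. RCP2.6 / RCP4.5 / RCP6.0 / RCP8.5
    temp_delta: float = 0.0
    precip_factor: float = 1.0
    seasonality_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.period not in ("baseline", "2050s", "2070s"):
            raise SchemaError(f"unknown period {self.period!r}")
        if self.period == "baseline" and (
            self.temp_delta != 0.0
            or self.precip_factor != 1.0
            or self.seasonality_delta != 0.0
        ):
            raise SchemaError("baseline scenario must have identity deltas")

    @property
    def is_baseline(self) -> bool:
        return self.period == "baseline"


BASELINE = ScenarioSpec(name="baseline")


@dataclass(frozen=True)
class VirtualSpecies:
    """A species with a known Gaussian niche in the 5-dim climate space.

    Suitability at a cell with climate x is the product over variables k of
    ``exp(-(x_k - opt_k)^2 / (2 * breadth_k^2))`` — each factor in (0, 1],
    maximized exactly at ``niche_optimum``.
    """

    species_id: str
    niche_optimum: tuple[float, ...]
    niche_breadth: tuple[float, ...]
    prevalence: float = 0.03
    n_occurrences: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.niche_optimum) != len(CLIMATE_VARS):
            raise SchemaError("niche_optimum must have one value per climate variable")
        if len(self.niche_breadth) != len(CLIMATE_VARS):
            raise SchemaError("niche_breadth must have one value per climate variable")
        if any(b <= 0 for b in self.niche_breadth):
            raise SchemaError("niche breadths must be positive")
        if self.n_occurrences < 10:
            # inclusion rule: species with fewer than ten distinct records
            # are not modelled
            raise SchemaError(
                f"n_occurrences must be >= 10, got {self.n_occurrences}"
            )


# ---------------------------------------------------------------------------
# elevation models
# ---------------------------------------------------------------------------

def _elevation(grid: GridSpec) -> np.ndarray:
    """Deterministic elevation surface selected by ``grid.elevation_model``.

    ``ridge_west`` (default): a north-south mountain ridge in the western
    third of the domain, its crest modulated along latitude so it carries
    peaks separated by saddles (ranges that contract upslope break into
    disjoint summit patches), on top of a gentle west-high/east-low slope.
    ``ridge_east`` mirrors it; ``flat`` is all zeros.
    """
    lon, lat = grid.cell_centers()
    lon_span = grid.n_cols * grid.cell_size
    lat_span = grid.n_rows * grid.cell_size
    x = (lon - grid.origin_lon) / lon_span          # 0 west .. 1 east
    y = (grid.origin_lat - lat) / lat_span          # 0 north .. 1 south

    model = grid.elevation_model
    if model == "flat":
        return np.zeros(grid.shape)
    if model == "ridge_east":
        x = 1.0 - x
    elif model != "ridge_west":
        raise SchemaError(f"unknown elevation_model {model!r}")

    ridge = 3500.0 * np.exp(-(((x - 0.22) / 0.16) ** 2))
    # peaks and saddles along the crest, with a period much shorter than a
    # species' latitudinal range span: local geometry then averages out of
    # centroid shifts while the saddles still break a contracting summit
    # band into disjoint patches
    modulation = 0.70 + 0.30 * np.cos(2.0 * np.pi * y * 12.0)
    slope = 600.0 * (1.0 - x)  # west high, east low
    return ridge * modulation + slope


# ---------------------------------------------------------------------------
# climate stack
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float, std: float) -> np.ndarray:
    """Smoothed Gaussian random field rescaled to the requested std-dev."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    s = raw.std()
    if s == 0:
        return np.zeros(shape)
    return raw * (std / s)


def make_climate_stack(
    grid: GridSpec,
    scenario: ScenarioSpec = BASELINE,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> ClimateStack:
    """Generate the five climate layers plus elevation for one scenario.

    Baseline layers are a deterministic function of (grid, seed): temperature
    decreases with latitude (LAT_GRADIENT) and with elevation (LAPSE_RATE),
    plus spatially autocorrelated noise; precipitation is an independent
    smoothed field over a longitudinal gradient.  A future scenario equals
    the baseline with the scenario deltas applied cell-wise, so the
    future-minus-baseline difference is exactly the delta everywhere.
    Bit-deterministic given (grid, scenario, seed).
    """
    lon, lat = grid.cell_centers()
    elev = _elevation(grid)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2161]))
    shape = grid.shape
    noise_sigma = max(2.0, min(grid.n_rows, grid.n_cols) / 20.0)

    # reference latitude = southern edge so temperature is warmest in the south
    lat_south = grid.origin_lat - grid.n_rows * grid.cell_size
    tmean = (
        24.0
        - LAT_GRADIENT * (lat - lat_south)
        - LAPSE_RATE * elev / 1000.0
        + _smooth_field(rng, shape, noise_sigma, 0.7)
    )

    lon_span = grid.n_cols * grid.cell_size
    x = (lon - grid.origin_lon) / lon_span
    precip = np.clip(
        1400.0
        - 600.0 * x  # wetter west (orographic), drier east
        - 250.0 * (elev / 3500.0)
        + _smooth_field(rng, shape, noise_sigma, 140.0),
        0.0,
        None,
    )

    # seasonality follows continentality (east-west), not latitude: the
    # interior east of the domain has a more extreme annual cycle.  Keeping
    # the latitude structure out of this layer matters because it does not
    # change under a warming scenario, and any latitudinal gradient in a
    # scenario-static layer would act as a spurious stand-in for temperature.
    seasonality = (
        420.0
        + 160.0 * x
        + _smooth_field(rng, shape, noise_sigma, 40.0)
    )
    # annual spread between the coldest-month minimum and warmest-month
    # maximum; tied to seasonality plus an independent term so the six layers
    # are correlated but not collinear
    spread = 8.0 + seasonality / 100.0 + _smooth_field(rng, shape, noise_sigma, 2.0)
    tmin = tmean - spread
    tmax = tmean + spread

    layers = {
        "annual_precip": precip,
        "annual_mean_temp": tmean,
        "temp_seasonality": seasonality,
        "min_temp_coldest": tmin,
        "max_temp_warmest": tmax,
        "elevation": elev,
    }

    if not scenario.is_baseline:
        for name in TEMP_LAYERS:
            layers[name] = layers[name] + scenario.temp_delta
        layers["annual_precip"] = layers["annual_precip"] * scenario.precip_factor
        layers["temp_seasonality"] = (
            layers["temp_seasonality"] + scenario.seasonality_delta
        )

    return ClimateStack(grid=grid, layers=layers, mask=mask, scenario=scenario.name)


# ---------------------------------------------------------------------------
# virtual species
# ---------------------------------------------------------------------------

def species_suitability(vs: VirtualSpecies, stack: ClimateStack) -> SuitabilityMap:
    """True (noise-free) suitability of a virtual species on a stack.

    Per-cell value = prod_k exp(-(x_k - opt_k)^2 / (2 breadth_k^2)); exactly 1
    where the cell climate equals the niche optimum.
    """
    missing = [v for v in CLIMATE_VARS if v not in stack.layers]
    if missing:
        raise SchemaError(f"stack missing climate variables: {missing}")
    x = stack.climate_matrix()  # (n_cells, 5)
    opt = np.asarray(vs.niche_optimum, dtype=float)
    br = np.asarray(vs.niche_breadth, dtype=float)
    z = (x - opt) / br
    values = np.exp(-0.5 * np.sum(z * z, axis=1)).reshape(stack.grid.shape)
    values = np.where(stack.mask, values, 0.0)
    return SuitabilityMap(
        species_id=vs.species_id, scenario=stack.scenario,
        grid=stack.grid, values=values, mask=stack.mask,
    )


def sample_occurrences(
    vs: VirtualSpecies, truth: SuitabilityMap, seed: int
) -> "pd.DataFrame":
    """Sample occurrence records from the true suitability surface.

    Cells are drawn without replacement with probability proportional to
    their true suitability (one record per distinct cell, mirroring
    'different geo-referenced occurrences'); records carry the cell-center
    coordinates.  Deterministic given the seed.

    Returns a DataFrame with columns ``species, lon, lat``.
    """
    import pandas as pd

    flat = np.where(truth.mask.ravel(), truth.values.ravel(), 0.0)
    support = np.flatnonzero(flat > 0)
    n = vs.n_occurrences
    if n > support.size:
        raise InfeasibleSampleError(
            f"requested {n} occurrences but only {support.size} cells "
            "have positive suitability"
        )
    p = flat[support] / flat[support].sum()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7919]))
    chosen = rng.choice(support, size=n, replace=False, p=p)
    rows, cols = np.unravel_index(chosen, truth.grid.shape)
    lons = truth.grid.origin_lon + (cols + 0.5) * truth.grid.cell_size
    lats = truth.grid.origin_lat - (rows + 0.5) * truth.grid.cell_size
    return pd.DataFrame(
        {"species": vs.species_id, "lon": lons, "lat": lats}
    )


def calibrate_breadth(
    optimum: np.ndarray,
    stack: ClimateStack,
    prevalence: float,
    relative_breadth: np.ndarray | None = None,
) -> np.ndarray:
    """Scale niche breadths so the expected suitable fraction hits a target.

    Breadths are ``s * scale_k`` with ``scale_k`` the per-variable std-dev of
    the baseline climate over unmasked cells (optionally weighted by
    ``relative_breadth``); the common factor s is found by bisection so that
    the mean suitability over unmasked cells — the expected fraction of the
    grid suitable — equals ``prevalence``.  Calibrating on the mean rather
    than on a hard suitability level controls the tail mass of the surface,
    which is what makes a niche informative to a presence-background model.
    Deterministic.
    """
    x = stack.climate_matrix()[stack.unmasked_indices()]
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    if relative_breadth is not None:
        scale = scale * np.asarray(relative_breadth, dtype=float)
    z2 = ((x - optimum) / scale) ** 2

    def frac_suitable(s: float) -> float:
        suit = np.exp(-0.5 * np.sum(z2, axis=1) / (s * s))
        return float(np.mean(suit))

    lo, hi = 1e-3, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac_suitable(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) * scale


#: Relative niche breadths making species temperature-limited: the thermal
#: variables (annual mean, coldest-month min, warmest-month max) get narrow
#: tolerances while precipitation and seasonality get 3x wider ones, so the
#: suitable region tracks temperature isotherms and moves poleward/upslope
#: under warming rather than being pinned by the water layers.
TEMPERATURE_TRACKING_BREADTH = (3.0, 1.0, 3.0, 1.0, 1.0)


def make_virtual_species(
    stack: ClimateStack,
    species_id: str,
    seed: int,
    anchor_pool: np.ndarray,
    prevalence: float = 0.03,
    n_occurrences: int = 100,
    relative_breadth: tuple[float, ...] = TEMPERATURE_TRACKING_BREADTH,
) -> VirtualSpecies:
    """Build a virtual species anchored at a random cell of ``anchor_pool``.

    The niche optimum is the baseline climate of the anchor cell (suitability
    is exactly 1 there); breadths are calibrated so about ``prevalence`` of
    the grid is suitable at the 0.5 level.  ``anchor_pool`` is an array of
    flat cell indices — restricting it (e.g. to montane or to warm lowland
    cells) yields ecologically distinct guilds.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4409]))
    anchor = int(rng.choice(anchor_pool))
    optimum = stack.climate_matrix()[anchor]
    breadth = calibrate_breadth(
        optimum, stack, prevalence,
        relative_breadth=np.asarray(relative_breadth, dtype=float),
    )
    return VirtualSpecies(
        species_id=species_id,
        niche_optimum=tuple(float(v) for v in optimum),
        niche_breadth=tuple(float(v) for v in breadth),
        prevalence=prevalence,
        n_occurrences=n_occurrences,
        seed=seed,
    )
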