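"""Per-species range-change statistics between current and future range maps.

Areas are raw grid-cell counts (no latitudinal area correction).  With
A_c / A_f the current/future occupied-cell counts and DS_fc the overlap:

    AC  = (A_f - A_c) / A_c * 100        area change, %
    DSL = (A_c - DS_fc) / A_c * 100      distribution space loss, %
    NDS = (A_f - DS_fc) / A_f * 100      new distribution space, %

The "geometric mean point" of a range is the unweighted centroid of its
presence-cell centers; range movement is reported as the future-minus-current
centroid shift (degrees), its Euclidean norm, and its compass bearing.
Altitude statistics are the mean and min-max of elevation over presence cells.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import UndefinedMetricError
from .grids import GridSpec, RangeMap, check_same_grid


@dataclass
class RangeShiftMetrics:
    """All range-change indicators for one species under one scenario."""

    species_id: str
    scenario: str
    A_c: int
    A_f: int
    DS_fc: int
    AC: float
    DSL: float
    NDS: float | None  # undefined (None) when the future range is empty
    lon_current: float
    lat_current: float
    lon_future: float
    lat_future: float
    lat_shift: float  # + = north
    lon_shift: float  # + = east
    shift_distance: float  # degrees
    shift_bearing: float  # degrees clockwise from north, [0, 360)
    alt_current_mean: float
    alt_future_mean: float
    alt_change: float
    alt_current_min: float
    alt_current_max: float
    alt_future_min: float
    alt_future_max: float
    ci_change: float | None = None  # filled in by the fragmentation stage

    def as_dict(self) -> dict:
        return asdict(self)


def area_change(
    current: RangeMap, future: RangeMap
) -> tuple[int, int, int, float, float, float | None]:
    """Area bookkeeping between two range maps: (A_c, A_f, DS_fc, AC, DSL, NDS).

    A_c = 0 is an error (no current range to compare against).  A_f = 0 gives
    AC = -100 and DSL as usual, but NDS is undefined and returned as None —
    never as a silent NaN.
    """
    check_same_grid(current.grid, future.grid)
    a_c, a_f = current.area, future.area
    if a_c == 0:
        raise UndefinedMetricError(
            f"species '{current.species_id}': current range is empty"
        )
    ds_fc = int((current.presence & future.presence).sum())
    ac = (a_f - a_c) / a_c * 100.0
    dsl = (a_c - ds_fc) / a_c * 100.0
    nds = (a_f - ds_fc) / a_f * 100.0 if a_f > 0 else None
    return a_c, a_f, ds_fc, ac, dsl, nds


def _centroid(r: RangeMap) -> tuple[float, float]:
    if r.area == 0:
        raise UndefinedMetricError(
            f"species '{r.species_id}': centroid of an empty range is undefined"
        )
    rows, cols = np.nonzero(r.presence)
    lon = r.grid.origin_lon + (cols + 0.5) * r.grid.cell_size
    lat = r.grid.origin_lat - (rows + 0.5) * r.grid.cell_size
    return float(lon.mean()), float(lat.mean())


def centroid_shift(
    current: RangeMap, future: RangeMap
) -> tuple[float, float, float, float]:
    """Movement of the range centroid: (lat_shift, lon_shift, distance, bearing).

    Shifts are future minus current in degrees; distance is the Euclidean
    norm in degree space; bearing = atan2(lon_shift, lat_shift) in degrees
    clockwise from north, in [0, 360).
    """
    check_same_grid(current.grid, future.grid)
    lon_c, lat_c = _centroid(current)
    lon_f, lat_f = _centroid(future)
    lat_shift, lon_shift = lat_f - lat_c, lon_f - lon_c
    distance = float(np.hypot(lat_shift, lon_shift))
    bearing = float(np.degrees(np.arctan2(lon_shift, lat_shift)) % 360.0)
    return lat_shift, lon_shift, distance, bearing


def great_circle_km(lon1, lat1, lon2, lat2) -> float:
    """Haversine distance between two lon/lat points, km (spherical Earth)."""
    r = 6371.0088
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp, dl = p2 - p1, np.radians(lon2 - lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * r * np.arcsin(np.sqrt(a)))


def altitude_metrics(r: RangeMap, elevation: np.ndarray) -> tuple[float, float, float]:
    """(mean, min, max) elevation over presence cells."""
    elevation = np.asarray(elevation, dtype=float)
    if elevation.shape != r.grid.shape:
        raise UndefinedMetricError("elevation layer not on the range map's grid")
    if r.area == 0:
        raise UndefinedMetricError(
            f"species '{r.species_id}': altitude of an empty range is undefined"
        )
    vals = elevation[r.presence]
    return float(vals.mean()), float(vals.min()), float(vals.max())


def compute_metrics(
    current: RangeMap, future: RangeMap, elevation: np.ndarray
) -> RangeShiftMetrics:
    """All range-shift indicators for one species between two scenarios."""
    a_c, a_f, ds_fc, ac, dsl, nds = area_change(current, future)
    lon_c, lat_c = _centroid(current)
    alt_c_mean, alt_c_min, alt_c_max = altitude_metrics(current, elevation)
    if a_f > 0:
        lat_shift, lon_shift, dist, bearing = centroid_shift(current, future)
        lon_f, lat_f = _centroid(future)
        alt_f_mean, alt_f_min, alt_f_max = altitude_metrics(future, elevation)
    else:
        lat_shift = lon_shift = dist = bearing = float("nan")
        lon_f = lat_f = alt_f_mean = alt_f_min = alt_f_max = float("nan")
    return RangeShiftMetrics(
        species_id=current.species_id,
        scenario=future.scenario,
        A_c=a_c, A_f=a_f, DS_fc=ds_fc, AC=ac, DSL=dsl, NDS=nds,
        lon_current=lon_c, lat_current=lat_c,
        lon_future=lon_f, lat_future=lat_f,
        lat_shift=lat_shift, lon_shift=lon_shift,
        shift_distance=dist, shift_bearing=bearing,
        alt_current_mean=alt_c_mean, alt_future_mean=alt_f_mean,
        alt_change=alt_f_mean - alt_c_mean,
        alt_current_min=alt_c_min, alt_current_max=alt_c_max,
        alt_future_min=alt_f_min, alt_future_max=alt_f_max,
    )


# ---------------------------------------------------------------------------
# assemblage summary (Table-1-style)
# ---------------------------------------------------------------------------

def _safe_pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p; (nan, nan) when either side has zero
    variance — degenerate correlations are reported as undefined, never 0."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = pearsonr(x, y)
    return float(r), float(p)


def summarize_assemblage(
    metrics: list[RangeShiftMetrics],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cross-species summary per scenario, plus a correlation table.

    Returns (per_species, summary, correlations):

    * per_species — one row per species x scenario with every indicator;
    * summary — per scenario: % of species shifting north / west / upslope,
      mean shifts, mean DSL/NDS, counts of large longitudinal movers, and
      mean CI change split by declining (AC < 0) vs expanding (AC > 0)
      species when CI change is available;
    * correlations — Pearson r and two-sided p of area change (cells) and
      area-change ratio (%) against current area/latitude/longitude/altitude
      and the latitude/longitude/altitude/NDS/DSL/CI changes.  Omitted (with
      a warning) for scenarios with fewer than 3 species.
    """
    if not metrics:
        raise UndefinedMetricError("no metrics to summarize")
    per_species = pd.DataFrame([m.as_dict() for m in metrics])

    summaries, corr_rows = [], []
    for scenario, grp in per_species.groupby("scenario", sort=True):
        n = len(grp)
        row = {
            "scenario": scenario,
            "n_species": n,
            "pct_north": float(np.mean(grp["lat_shift"] > 0) * 100),
            "pct_west": float(np.mean(grp["lon_shift"] < 0) * 100),
            "pct_upslope": float(np.mean(grp["alt_change"] > 0) * 100),
            "mean_lat_shift": float(grp["lat_shift"].mean()),
            "mean_lon_shift": float(grp["lon_shift"].mean()),
            "mean_alt_change": float(grp["alt_change"].mean()),
            "mean_AC": float(grp["AC"].mean()),
            "mean_DSL": float(grp["DSL"].mean()),
            "mean_NDS": float(grp["NDS"].dropna().mean()),
            "n_lon_shift_gt_0.5": int((grp["lon_shift"].abs() > 0.5).sum()),
            "n_lon_shift_gt_1.0": int((grp["lon_shift"].abs() > 1.0).sum()),
            "n_DSL_gt_50": int((grp["DSL"] > 50).sum()),
            "n_NDS_gt_50": int((grp["NDS"] > 50).sum()),
        }
        if grp["ci_change"].notna().any():
            declining = grp.loc[grp["AC"] < 0, "ci_change"].dropna()
            expanding = grp.loc[grp["AC"] > 0, "ci_change"].dropna()
            row["mean_ci_change_declining"] = (
                float(declining.mean()) if len(declining) else float("nan")
            )
            row["mean_ci_change_expanding"] = (
                float(expanding.mean()) if len(expanding) else float("nan")
            )
        summaries.append(row)

        if n < 3:
            import warnings

            warnings.warn(
                f"scenario '{scenario}': fewer than 3 species, "
                "correlations omitted",
                stacklevel=2,
            )
            continue
        area_change_cells = (grp["A_f"] - grp["A_c"]).to_numpy(float)
        targets = {
            "area_change": area_change_cells,
            "area_change_ratio": grp["AC"].to_numpy(float),
        }
        predictors = {
            "current_area": grp["A_c"].to_numpy(float),
            "current_latitude": grp["lat_current"].to_numpy(float),
            "current_longitude": grp["lon_current"].to_numpy(float),
            "current_altitude": grp["alt_current_mean"].to_numpy(float),
            "latitude_change": grp["lat_shift"].to_numpy(float),
            "longitude_change": grp["lon_shift"].to_numpy(float),
            "altitude_change": grp["alt_change"].to_numpy(float),
            "new_distribution_space": grp["NDS"].to_numpy(float),
            "distribution_space_loss": grp["DSL"].to_numpy(float),
            "ci_change": grp["ci_change"].to_numpy(float),
        }
        for pname, pvals in predictors.items():
            for tname, tvals in targets.items():
                r, p = _safe_pearson(pvals, tvals)
                corr_rows.append(
                    {"scenario": scenario, "parameter": pname,
                     "against": tname, "pearson_r": r, "p_value": p}
                )

    summary = pd.DataFrame(summaries)
    correlations = pd.DataFrame(
        corr_rows,
        columns=["scenario", "parameter", "against", "pearson_r", "p_value"],
    )
    return per_species, summary, correlations
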