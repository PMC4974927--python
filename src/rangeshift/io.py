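"""Readers and writers: ESRI ASCII grids, occurrence CSVs, fit sidecars.

Rasters are stored one band per file in the ESRI ASCII grid format (a
six-line header followed by whitespace-separated rows, north to south) —
a plain-text format readable by every GIS.  A climate stack is a directory
with one ``<variable>.asc`` per band.  Occurrence tables are CSV with the
header ``species,lon,lat``.  All writers use fixed number formatting so a
rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError
from .grids import ALL_VARS, ClimateStack, GridSpec, RangeMap, SuitabilityMap
from .sdm import FeatureScaling, ReplicateFit, SdmFit

NODATA = -9999.0
_FMT = "%.10g"


# ---------------------------------------------------------------------------
# ESRI ASCII grids
# ---------------------------------------------------------------------------

def write_ascii_grid(path: str | Path, values: np.ndarray, grid: GridSpec,
                     nodata_mask: np.ndarray | None = None) -> None:
    """Write one band as an ESRI ASCII grid (cell-center registration)."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise AlignmentError(f"values shape {values.shape} != grid {grid.shape}")
    out = values.copy()
    if nodata_mask is not None:
        out[~np.asarray(nodata_mask, dtype=bool)] = NODATA
    yll = grid.origin_lat - grid.n_rows * grid.cell_size
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {_FMT % grid.origin_lon}",
        f"yllcorner {_FMT % yll}",
        f"cellsize {_FMT % grid.cell_size}",
        f"NODATA_value {_FMT % NODATA}",
    ]
    lines += [" ".join(_FMT % v for v in row) for row in out]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(
    path: str | Path, elevation_model: str = "ridge_west"
) -> tuple[np.ndarray, GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid -> (values, grid, valid_mask)."""
    text = Path(path).read_text().strip().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise SchemaError(f"{path}: missing '{key}' in ASCII grid header")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = np.loadtxt(text[i:], dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (n_rows, n_cols):
        raise SchemaError(
            f"{path}: data shape {values.shape} does not match header "
            f"({n_rows}, {n_cols})"
        )
    nodata = header.get("nodata_value", NODATA)
    mask = values != nodata
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * header["cellsize"],
        cell_size=header["cellsize"],
        elevation_model=elevation_model,
    )
    return values, grid, mask


# ---------------------------------------------------------------------------
# climate stacks
# ---------------------------------------------------------------------------

def write_stack(stack: ClimateStack, out_dir: str | Path) -> None:
    """Write one ``<variable>.asc`` per band into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for var in ALL_VARS:
        write_ascii_grid(out / f"{var}.asc", stack.layers[var], stack.grid,
                         nodata_mask=stack.mask)


def read_stack(stack_dir: str | Path, scenario: str | None = None,
               elevation_model: str = "ridge_west") -> ClimateStack:
    """Read a stack directory; all bands must share one grid (else alignment
    error)."""
    stack_dir = Path(stack_dir)
    layers: dict[str, np.ndarray] = {}
    grid: GridSpec | None = None
    mask: np.ndarray | None = None
    for var in ALL_VARS:
        path = stack_dir / f"{var}.asc"
        if not path.exists():
            raise SchemaError(f"stack directory {stack_dir} missing {var}.asc")
        values, g, m = read_ascii_grid(path, elevation_model=elevation_model)
        if grid is None:
            grid, mask = g, m
        else:
            if g != grid:
                raise AlignmentError(
                    f"band '{var}' is on a shifted or mismatched grid"
                )
            mask = mask & m
        layers[var] = values
    assert grid is not None
    return ClimateStack(
        grid=grid, layers=layers, mask=mask,
        scenario=scenario or stack_dir.name,
    )


# ---------------------------------------------------------------------------
# suitability / range maps
# ---------------------------------------------------------------------------

def write_suitability(s: SuitabilityMap, path: str | Path) -> None:
    write_ascii_grid(path, s.values, s.grid, nodata_mask=s.mask)


def write_range_map(r: RangeMap, path: str | Path) -> None:
    write_ascii_grid(path, r.presence.astype(float), r.grid)


def read_range_map(path: str | Path, species_id: str, scenario: str) -> RangeMap:
    values, grid, mask = read_ascii_grid(path)
    presence = (values == 1.0) & mask
    return RangeMap(species_id=species_id, scenario=scenario, grid=grid,
                    presence=presence)


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

def write_occurrences(occ: pd.DataFrame, path: str | Path) -> None:
    occ.to_csv(path, index=False, float_format=_FMT)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read and validate an occurrence CSV (header ``species,lon,lat``).

    Malformed rows and out-of-bounds coordinates are rejected with the
    offending line number (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path)
    required = ["species", "lon", "lat"]
    if list(df.columns[:3]) != required:
        raise SchemaError(
            f"{path}: expected header 'species,lon,lat', got {list(df.columns)}"
        )
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = (
        lon.isna() | lat.isna()
        | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
    )
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise SchemaError(f"{path}: malformed or out-of-bounds row at line {line}")
    df["lon"], df["lat"] = lon, lat
    return df


def split_by_species(occ: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {str(sp): grp.reset_index(drop=True)
            for sp, grp in occ.groupby("species", sort=True)}


# ---------------------------------------------------------------------------
# fit sidecars
# ---------------------------------------------------------------------------

def write_fit(fit: SdmFit, path: str | Path) -> None:
    """Serialize a fitted model (weights, scaling, threshold, AUCs) as JSON."""
    payload = {
        "species_id": fit.species_id,
        "threshold": fit.threshold,
        "feature_names": list(fit.feature_names),
        "scaling": {"mins": fit.scaling.mins.tolist(),
                    "maxs": fit.scaling.maxs.tolist()},
        "regularization": fit.regularization.tolist(),
        "replicate_aucs": fit.replicate_aucs.tolist(),
        "auc_mean": float(np.mean(fit.replicate_aucs)),
        "auc_min": float(np.min(fit.replicate_aucs)),
        "auc_max": float(np.max(fit.replicate_aucs)),
        "replicates": [
            {"weights": r.weights.tolist(), "center": r.center}
            for r in fit.replicates
        ],
        "presence_cells": fit.presence_cells.tolist(),
        "background_cells": fit.background_cells.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_fit(path: str | Path) -> SdmFit:
    d = json.loads(Path(path).read_text())
    return SdmFit(
        species_id=d["species_id"],
        scaling=FeatureScaling(
            mins=np.array(d["scaling"]["mins"]),
            maxs=np.array(d["scaling"]["maxs"]),
        ),
        replicates=[
            ReplicateFit(weights=np.array(r["weights"]), center=float(r["center"]))
            for r in d["replicates"]
        ],
        replicate_aucs=np.array(d["replicate_aucs"]),
        threshold=float(d["threshold"]),
        regularization=np.array(d["regularization"]),
        background_cells=np.array(d["background_cells"], dtype=int),
        presence_cells=np.array(d["presence_cells"], dtype=int),
        feature_names=tuple(d["feature_names"]),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV writer with fixed float formatting (byte-stable across reruns)."""
    df.to_csv(path, index=False, float_format=_FMT)
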