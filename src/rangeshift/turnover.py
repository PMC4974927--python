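"""Grid-cell species turnover over an assemblage of range maps.

Per cell, with NT the current species count, NC the newly occurring species
(absent now, present in the future) and NE the locally extinct species
(present now, absent in the future):

    TS = NC + NE                     turnover sum (count)
    TR = TS / (NT + NC) * 100        turnover ratio (%)

TR is undefined (masked) where NT + NC = 0 — it is never coerced to 0.
Priority areas are cells jointly exceeding a TR and a TS threshold
(strict inequalities; defaults TR > 50, TS > 20), grouped into connected
regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import AlignmentError
from .grids import GridSpec, RangeMap, check_same_grid


@dataclass
class TurnoverMap:
    """Per-cell assemblage turnover surfaces (NT, NC, NE, TS, TR)."""

    grid: GridSpec
    NT: np.ndarray  # current richness
    NC: np.ndarray  # colonizations
    NE: np.ndarray  # local extinctions
    TS: np.ndarray  # turnover sum
    TR: np.ndarray  # turnover ratio, %; NaN where undefined
    tr_defined: np.ndarray  # mask: NT + NC > 0


def _stack(maps: list[RangeMap]) -> tuple[GridSpec, np.ndarray]:
    if not maps:
        raise AlignmentError("empty range-map list")
    grid = check_same_grid(*[m.grid for m in maps])
    return grid, np.stack([m.presence for m in maps])


def richness_map(maps: list[RangeMap]) -> np.ndarray:
    """Per-cell species count over an assemblage of range maps."""
    _, arr = _stack(maps)
    return arr.sum(axis=0).astype(int)


def build_turnover(
    current_maps: list[RangeMap], future_maps: list[RangeMap]
) -> TurnoverMap:
    """Cell-wise turnover bookkeeping between matched current/future stacks.

    The two lists must be equal length, in matched species order, on a
    shared grid.
    """
    if len(current_maps) != len(future_maps):
        raise AlignmentError(
            f"{len(current_maps)} current vs {len(future_maps)} future maps"
        )
    for c, f in zip(current_maps, future_maps):
        if c.species_id != f.species_id:
            raise AlignmentError(
                f"species order mismatch: '{c.species_id}' vs '{f.species_id}'"
            )
    grid, cur = _stack(current_maps)
    grid_f, fut = _stack(future_maps)
    check_same_grid(grid, grid_f)

    nt = cur.sum(axis=0).astype(int)
    nc = (~cur & fut).sum(axis=0).astype(int)
    ne = (cur & ~fut).sum(axis=0).astype(int)
    ts = nc + ne
    denom = nt + nc
    defined = denom > 0
    tr = np.full(grid.shape, np.nan)
    tr[defined] = ts[defined] / denom[defined] * 100.0
    return TurnoverMap(grid=grid, NT=nt, NC=nc, NE=ne, TS=ts, TR=tr,
                       tr_defined=defined)


def connectivity_structure(connectivity: int) -> np.ndarray:
    """Adjacency footprint for connected-component labeling (4 or 8)."""
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise AlignmentError(f"connectivity must be 4 or 8, got {connectivity}")


def auto_thresholds(t: TurnoverMap) -> tuple[float, float]:
    """Half of the observed maxima of TR and TS, the half-maximum criterion."""
    tr_max = float(np.nanmax(t.TR)) if t.tr_defined.any() else 0.0
    return tr_max / 2.0, float(t.TS.max()) / 2.0


def priority_areas(
    t: TurnoverMap,
    tr_min: float = 50.0,
    ts_min: float = 20.0,
    connectivity: int = 8,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Cells with TR > tr_min AND TS > ts_min (both strict), as hotspot mask
    plus a table of connected regions (id, cell count, bounding box).
    """
    with np.errstate(invalid="ignore"):
        hot = t.tr_defined & (t.TR > tr_min) & (t.TS > ts_min)
    labels, n = ndimage.label(hot, structure=connectivity_structure(connectivity))
    rows = []
    for region_id, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        cells = int((labels[sl] == region_id).sum())
        rows.append(
            {
                "region_id": region_id,
                "n_cells": cells,
                "row_min": sl[0].start, "row_max": sl[0].stop - 1,
                "col_min": sl[1].start, "col_max": sl[1].stop - 1,
            }
        )
    regions = pd.DataFrame(
        rows, columns=["region_id", "n_cells", "row_min", "row_max",
                       "col_min", "col_max"],
    )
    return hot, regions
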