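"""Range fragmentation: patch labeling and the coherence index.

Patches are maximal connected components of the presence raster (8-neighbor
adjacency by default, 4-neighbor by flag).  Fragmentation is summarized by
the coherence index

    CI = sum_i (A_i / A_t)^2

over patch areas A_i (cell counts) with A_t the total occupied area: the
probability that two individuals dropped uniformly at random on the range
land in the same patch.  CI = 1 for a single patch, 1/n for n equal patches;
an increase in CI means fragmentation decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import UndefinedMetricError
from .grids import RangeMap
from .turnover import connectivity_structure


@dataclass
class PatchSet:
    """Patch decomposition of one species x scenario range map."""

    species_id: str
    scenario: str
    n_patches: int
    patch_areas: list[int]
    A_t: int
    labels: np.ndarray  # labeled raster, 0 = background
    connectivity: int = 8

    @property
    def ci(self) -> float:
        return coherence_index(self)


def label_patches(r: RangeMap, connectivity: int = 8) -> PatchSet:
    """Partition presence cells into connected patches.

    An empty range yields an empty PatchSet (n_patches = 0); its CI is
    undefined and raises when requested.
    """
    structure = connectivity_structure(connectivity)
    labels, n = ndimage.label(r.presence, structure=structure)
    if n == 0:
        areas: list[int] = []
    else:
        areas = np.bincount(labels.ravel())[1:].tolist()
    return PatchSet(
        species_id=r.species_id,
        scenario=r.scenario,
        n_patches=int(n),
        patch_areas=[int(a) for a in areas],
        A_t=int(sum(areas)),
        labels=labels,
        connectivity=connectivity,
    )


def coherence_index(p: PatchSet) -> float:
    """CI = sum_i (A_i / A_t)^2; undefined for an empty patch set."""
    if p.n_patches == 0 or p.A_t == 0:
        raise UndefinedMetricError(
            f"species '{p.species_id}': CI undefined for an empty range"
        )
    areas = np.asarray(p.patch_areas, dtype=float)
    return float(np.sum((areas / p.A_t) ** 2))


def ci_change(current: PatchSet, future: PatchSet) -> float:
    """Percent change of the coherence index: (CI_f - CI_c) / CI_c * 100."""
    ci_c = coherence_index(current)  # raises if undefined
    ci_f = coherence_index(future)
    return (ci_f - ci_c) / ci_c * 100.0
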