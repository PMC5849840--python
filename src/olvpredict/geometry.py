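"""Millimetre-true structure expansion, unions, volumes, fractional overlap.

The central statistic is the *fractional overlap* OLV = |parotid ∩ target| /
|parotid| by voxel count — a purely geometric quantity, computed on the
structure grid and independent of the dose grid.

Isotropic expansion is implemented with a Euclidean distance transform using
per-axis spacing, thresholded inclusively at the margin: a voxel belongs to
the expanded structure iff the distance from its center to the nearest
occupied voxel center is <= margin mm.  This is mm-true under anisotropic
voxels, unlike structuring-element dilation in voxel units.  Expansion never
enlarges the grid (clip at the array edge); generators and importers are
expected to pad grids so targets stay clear of the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .grid_io import StructureMask

__all__ = [
    "OverlapSpec",
    "distance_map_mm",
    "expand_mask",
    "union_masks",
    "volume_cc",
    "fractional_overlap",
]


@dataclass(frozen=True)
class OverlapSpec:
    """Which target an overlap is taken against and its expansion margin."""

    target: str  # e.g. "combined", "high", "intermediate", "low"
    margin_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.margin_mm < 0:
            raise ValueError(f"margin must be >= 0 mm, got {self.margin_mm}")


def distance_map_mm(m: StructureMask) -> np.ndarray:
    """Per-voxel Euclidean distance (mm) from each center to the nearest
    occupied voxel center; 0 inside the structure, +inf if it is empty."""
    if m.is_empty():
        return np.full(m.grid.shape, np.inf)
    return ndimage.distance_transform_edt(~m.occupancy, sampling=m.grid.spacing)


def expand_mask(m: StructureMask, margin_mm: float) -> StructureMask:
    """Isotropic mm expansion: occupied iff within ``margin_mm`` of the input."""
    if margin_mm < 0:
        raise ValueError(f"expansion margin must be >= 0 mm, got {margin_mm}")
    if margin_mm == 0 or m.is_empty():
        occ = m.occupancy.copy()
    else:
        occ = distance_map_mm(m) <= margin_mm
    name = m.name if margin_mm == 0 else f"{m.name}+{margin_mm:g}mm"
    return StructureMask(m.grid, occ, name)


def union_masks(masks: Sequence[StructureMask], name: str | None = None) -> StructureMask:
    """Voxelwise union; all masks must share one grid."""
    if len(masks) == 0:
        raise ValueError("union of an empty list of masks is undefined")
    grid = masks[0].grid
    for m in masks[1:]:
        if not grid.same_geometry(m.grid):
            raise ValueError(
                f"grid mismatch in union: '{masks[0].name}' vs '{m.name}'"
            )
    occ = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        occ |= m.occupancy
    if name is None:
        name = "+".join(m.name for m in masks)
    return StructureMask(grid, occ, name)


def volume_cc(m: StructureMask) -> float:
    """Occupied-voxel count x voxel volume, in cc."""
    return m.voxel_count * m.grid.voxel_volume_mm3 / 1000.0


def fractional_overlap(parotid: StructureMask, target: StructureMask) -> float:
    """|parotid ∩ target| / |parotid| by voxel count, in [0, 1]."""
    if not parotid.grid.same_geometry(target.grid):
        raise ValueError(
            f"grid mismatch: '{parotid.name}' vs '{target.name}'"
        )
    n_par = parotid.voxel_count
    if n_par == 0:
        raise ValueError(
            f"fractional overlap undefined: structure '{parotid.name}' is empty"
        )
    n_int = int(np.count_nonzero(parotid.occupancy & target.occupancy))
    return n_int / n_par
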