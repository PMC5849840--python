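"""Mean-dose and coverage statistics, and the plan-inclusion filter.

Only two dose scalars drive the analysis: a structure's mean dose D_mean
(the parotid sparing tolerance is 26 Gy) and a coverage fraction V_d (the
plan-acceptability criterion is V100% >= 90% for the highest-dose PTV;
equality is kept, since plans are excluded only for coverage *below* 90%).

When the structure and dose live on different grids, dose is sampled by
trilinear interpolation at the structure's occupied voxel centers; on an
identical grid this reduces exactly to direct voxel lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grid_io import DoseGrid, PlanMeta, StructureMask

__all__ = [
    "DoseStats",
    "sample_dose",
    "mean_dose",
    "coverage_fraction",
    "dose_stats",
    "filter_plans",
    "PAROTID_TOLERANCE_GY",
]

#: Parotid mean-dose sparing tolerance (Gy); a parotid counts "positive"
#: iff its D_mean is strictly greater than this.
PAROTID_TOLERANCE_GY = 26.0


@dataclass
class DoseStats:
    structure: str
    d_mean: float
    v_d: float | None = None
    query_dose: float | None = None

    def __post_init__(self) -> None:
        if self.d_mean < 0:
            raise ValueError("D_mean must be >= 0")
        if self.v_d is not None and not (0.0 <= self.v_d <= 1.0):
            raise ValueError("coverage fraction must lie in [0, 1]")


def sample_dose(d: DoseGrid, m: StructureMask) -> np.ndarray:
    """Dose values at every occupied voxel center of ``m``.

    Identical grids use direct lookup; otherwise trilinear interpolation.
    A structure voxel center outside the dose grid's bounding box is an
    error (no extrapolation), reported with its index and position.
    """
    if m.is_empty():
        raise ValueError(f"structure '{m.name}' is empty; dose sampling undefined")
    if m.grid.same_geometry(d.grid):
        return d.dose[m.occupancy]

    idx = np.argwhere(m.occupancy)
    pts = m.grid.voxel_centers(idx)
    axes = [d.grid.axis_coords(a) for a in range(3)]
    lo = np.array([ax[0] for ax in axes])
    hi = np.array([ax[-1] for ax in axes])
    outside = np.any((pts < lo - 1e-9) | (pts > hi + 1e-9), axis=1)
    if outside.any():
        bad = np.flatnonzero(outside)
        i0 = bad[0]
        raise ValueError(
            f"{bad.size} voxel center(s) of '{m.name}' fall outside the dose "
            f"grid bounding box; first offender: index {tuple(idx[i0])} at "
            f"{tuple(np.round(pts[i0], 3))} mm"
        )
    interp = RegularGridInterpolator(axes, d.dose, method="linear",
                                     bounds_error=False, fill_value=None)
    return interp(np.clip(pts, lo, hi))


def mean_dose(d: DoseGrid, m: StructureMask) -> float:
    """Mean dose (Gy) over the structure's occupied voxel centers."""
    return float(np.mean(sample_dose(d, m)))


def coverage_fraction(d: DoseGrid, m: StructureMask, threshold: float) -> float:
    """Fraction of occupied voxels with sampled dose >= threshold (inclusive)."""
    vals = sample_dose(d, m)
    return float(np.count_nonzero(vals >= threshold) / vals.size)


def dose_stats(d: DoseGrid, m: StructureMask, query_dose: float | None = None) -> DoseStats:
    v = coverage_fraction(d, m, query_dose) if query_dose is not None else None
    return DoseStats(m.name, mean_dose(d, m), v, query_dose)


@dataclass
class ExclusionEntry:
    plan_id: str
    reason: str
    v100: float | None = None


@dataclass
class FilterResult:
    included: list[PlanMeta]
    log: list[ExclusionEntry] = field(default_factory=list)


def filter_plans(plans: list[PlanMeta], min_coverage: float = 0.90) -> FilterResult:
    """Keep plans whose highest-PTV V100% is >= ``min_coverage``.

    Exclusions are logged by plan id with the offending value.  The clinical
    criterion also waives compromised coverage that falls outside the GTV;
    GTV geometry is not modeled here, so that clause is logged as
    not-evaluated rather than silently dropped.
    """
    included: list[PlanMeta] = []
    log: list[ExclusionEntry] = []
    for p in plans:
        if p.v100 is None:
            raise ValueError(f"plan '{p.plan_id}' carries no V100% coverage value")
        if p.v100 >= min_coverage:
            included.append(p)
        else:
            log.append(ExclusionEntry(
                p.plan_id,
                f"highest-PTV V100% = {p.v100:.3f} < {min_coverage:.2f} "
                "(GTV-overlap waiver not evaluated: no GTV geometry)",
                p.v100,
            ))
    return FilterResult(included, log)


def cumulative_dvh(d: DoseGrid, m: StructureMask,
                   edges: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Convenience cumulative DVH: (dose edges Gy, volume fraction >= edge)."""
    vals = sample_dose(d, m)
    if edges is None:
        edges = np.arange(0.0, float(vals.max()) + 1.0, 0.5)
    frac = np.array([np.count_nonzero(vals >= e) / vals.size for e in edges])
    return edges, frac
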