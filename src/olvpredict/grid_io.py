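"""Voxel-grid data model, planar-contour rasterization, and plan-bundle I/O.

All geometry lives on a regular 3-D lattice (:class:`VoxelGrid`) in physical
millimetres, axis order ``(x, y, z)``, 0-based indices.  The voxel with index
``(i, j, k)`` has its *center* at ``origin + (i*sx, j*sy, k*sz)``.  Structures
are boolean occupancy arrays (:class:`StructureMask`); dose is a nonnegative
Gy array (:class:`DoseGrid`) on a grid of its own.

A *plan bundle* is the package's open on-disk container: one directory per
plan holding each structure and the dose as single-volume NIfTI files plus a
``meta.json`` sidecar with grid geometry, prescription levels and the
highest-PTV V100% coverage.  It deliberately requires no clinical data format;
a DICOM importer would be an optional adapter on top of :class:`ContourSet`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "ContourSet",
    "StructureMask",
    "DoseGrid",
    "PlanMeta",
    "rasterize_contours",
    "write_plan_bundle",
    "load_plan_bundle",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D lattice: integer dims, positive mm spacing, mm origin.

    ``origin`` is the physical position of the center of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        if len(self.origin) != 3:
            raise ValueError(f"origin must be a triple, got {self.origin}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical center coordinates (mm) of every voxel along ``axis``."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to (n, 3) physical mm points."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class ContourSet:
    """A named structure as planar polygons: list of ``(z_mm, (n, 2) xy_mm)``.

    Polygons are implicitly closed (last vertex connects to the first).
    Several polygons may share one z plane; they combine by even-odd XOR at
    rasterization time, so holes and islands are honored.
    """

    name: str
    contours: list[tuple[float, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        norm = []
        for z, verts in self.contours:
            v = np.asarray(verts, dtype=float)
            if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
                raise ValueError(
                    f"contour at z={z} of '{self.name}' is degenerate: "
                    f"need >= 3 (x, y) vertices, got shape {v.shape}"
                )
            norm.append((float(z), v))
        self.contours = norm


@dataclass
class StructureMask:
    """Boolean occupancy of one named structure on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    occupancy: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.dtype != bool:
            occ = occ.astype(bool)
        if occ.shape != self.grid.shape:
            raise ValueError(
                f"occupancy shape {occ.shape} != grid dims {self.grid.shape} "
                f"for structure '{self.name}'"
            )
        self.occupancy = occ

    @property
    def voxel_count(self) -> int:
        return int(self.occupancy.sum())

    def is_empty(self) -> bool:
        return not self.occupancy.any()


@dataclass
class DoseGrid:
    """Nonnegative absorbed dose (Gy) per voxel on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dose, dtype=float)
        if d.shape != self.grid.shape:
            raise ValueError(f"dose shape {d.shape} != grid dims {self.grid.shape}")
        if np.any(d < 0):
            raise ValueError("dose must be nonnegative everywhere")
        self.dose = d


@dataclass
class PlanMeta:
    """Per-plan metadata: prescriptions, highest-PTV coverage, delivery notes.

    ``prescriptions`` are the simultaneously treated dose levels in Gy,
    strictly descending, 2-4 entries (e.g. ``(70, 59.4, 56)``).  ``v100`` is
    the fraction of the highest-dose PTV covered by its prescription dose.
    """

    plan_id: str
    prescriptions: tuple[float, ...]
    v100: float | None = None
    delivery: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.prescriptions = tuple(float(p) for p in self.prescriptions)
        if not (2 <= len(self.prescriptions) <= 4):
            raise ValueError(
                f"plan '{self.plan_id}': expected 2-4 prescription levels, "
                f"got {len(self.prescriptions)}"
            )
        if any(a <= b for a, b in zip(self.prescriptions, self.prescriptions[1:])):
            raise ValueError(
                f"plan '{self.plan_id}': prescriptions must be strictly "
                f"descending, got {self.prescriptions}"
            )
        if self.v100 is not None:
            self.v100 = float(self.v100)
            if not (0.0 <= self.v100 <= 1.0):
                raise ValueError(f"v100 must be in [0, 1], got {self.v100}")


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _points_in_polygon(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) inside test for flat point arrays.

    A point is inside iff a ray cast in +x crosses the polygon boundary an
    odd number of times.  Half-open edge intervals make shared vertices count
    once; points exactly on a horizontal edge follow the crossing convention.
    """
    x1 = verts[:, 0]
    y1 = verts[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    inside = np.zeros(px.shape, dtype=bool)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        crosses = (ey1 > py) != (ey2 > py)
        if not crosses.any():
            continue
        # x of edge/ray intersection; ey1 != ey2 wherever crosses is True
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = ex1 + (py - ey1) * (ex2 - ex1) / (ey2 - ey1)
        inside ^= crosses & (px < xint)
    return inside


def rasterize_contours(cs: ContourSet, grid: VoxelGrid) -> StructureMask:
    """Rasterize planar polygons to a voxel mask by the even-odd rule.

    A voxel is occupied iff its *center* lies inside an odd number of the
    polygons on its slice (same-slice polygons combine by XOR).  Each
    contour's z must lie within half a slice spacing of a grid slice; it
    snaps to that nearest slice.
    """
    occ = np.zeros(grid.shape, dtype=bool)
    if not cs.contours:
        return StructureMask(grid, occ, cs.name)

    sz = grid.spacing[2]
    zs = grid.axis_coords(2)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    px, py = np.meshgrid(xs, ys, indexing="ij")
    px = px.ravel()
    py = py.ravel()

    for z, verts in cs.contours:
        k = int(np.argmin(np.abs(zs - z)))
        if abs(zs[k] - z) > sz / 2 + 1e-9:
            raise ValueError(
                f"contour of '{cs.name}' at z={z:g} mm is farther than half a "
                f"slice spacing ({sz / 2:g} mm) from every grid slice"
            )
        inside = _points_in_polygon(px, py, verts).reshape(grid.dims[0], grid.dims[1])
        occ[:, :, k] ^= inside
    return StructureMask(grid, occ, cs.name)


# ---------------------------------------------------------------------------
# Plan bundles
# ---------------------------------------------------------------------------

def _safe_filename(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", name) or "structure"


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    aff[:3, 3] = grid.origin
    return aff


def _grid_to_json(grid: VoxelGrid) -> dict:
    return {"dims": list(grid.dims), "spacing": list(grid.spacing), "origin": list(grid.origin)}


def _grid_from_json(d: dict) -> VoxelGrid:
    return VoxelGrid(tuple(d["dims"]), tuple(d["spacing"]), tuple(d["origin"]))


def write_plan_bundle(
    path: str | Path,
    masks: Sequence[StructureMask],
    dose: DoseGrid | None,
    meta: PlanMeta,
) -> Path:
    """Write one plan as a directory of NIfTI volumes plus ``meta.json``."""
    path = Path(path)
    (path / "structures").mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for m in masks:
        fname = _safe_filename(m.name)
        if fname in files.values():  # disambiguate collisions after sanitizing
            fname = f"{fname}_{len(files)}"
        files[m.name] = fname
        img = nib.Nifti1Image(m.occupancy.astype(np.uint8), _affine(m.grid))
        nib.save(img, path / "structures" / f"{fname}.nii")

    doc = {
        "plan_id": meta.plan_id,
        "prescriptions": list(meta.prescriptions),
        "v100": meta.v100,
        "delivery": meta.delivery,
        "structures": [
            {"name": m.name, "file": files[m.name], "grid": _grid_to_json(m.grid)}
            for m in masks
        ],
        "dose_grid": _grid_to_json(dose.grid) if dose is not None else None,
    }
    if dose is not None:
        nib.save(nib.Nifti1Image(dose.dose.astype(np.float64), _affine(dose.grid)),
                 path / "dose.nii")
    (path / "meta.json").write_text(json.dumps(doc, indent=2))
    return path


def load_plan_bundle(
    path: str | Path, require_dose: bool = False
) -> tuple[list[StructureMask], DoseGrid | None, PlanMeta]:
    """Read a plan bundle; inverse of :func:`write_plan_bundle`.

    Raises if a stored array disagrees with the dims/spacing its header
    declares, or if ``require_dose`` is set and the bundle carries no dose.
    """
    path = Path(path)
    doc = json.loads((path / "meta.json").read_text())
    meta = PlanMeta(
        plan_id=doc["plan_id"],
        prescriptions=tuple(doc["prescriptions"]),
        v100=doc.get("v100"),
        delivery=doc.get("delivery", {}),
    )

    masks: list[StructureMask] = []
    for entry in doc["structures"]:
        grid = _grid_from_json(entry["grid"])
        img = nib.load(path / "structures" / f"{entry['file']}.nii")
        arr = np.asarray(img.dataobj)
        if arr.shape != grid.shape:
            raise ValueError(
                f"bundle '{meta.plan_id}': structure '{entry['name']}' array "
                f"shape {arr.shape} disagrees with declared dims {grid.shape}"
            )
        if not np.allclose(img.affine, _affine(grid)):
            raise ValueError(
                f"bundle '{meta.plan_id}': structure '{entry['name']}' affine "
                "disagrees with declared spacing/origin"
            )
        masks.append(StructureMask(grid, arr.astype(bool), entry["name"]))

    dose = None
    if doc.get("dose_grid") is not None:
        grid = _grid_from_json(doc["dose_grid"])
        img = nib.load(path / "dose.nii")
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if arr.shape != grid.shape:
            raise ValueError(
                f"bundle '{meta.plan_id}': dose array shape {arr.shape} "
                f"disagrees with declared dims {grid.shape}"
            )
        dose = DoseGrid(grid, arr)
    elif require_dose:
        raise ValueError(f"bundle '{meta.plan_id}' carries no dose volume")
    return masks, dose, meta
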