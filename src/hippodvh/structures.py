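"""Geometric data model: grids, planar contours, voxel masks.

Coordinates are patient-space millimetres. Grid axes carry anatomical
labels ("L-R", "A-P", "I-S", or the reversed forms "R-L", "P-A", "S-I")
identifying which array index runs along which body direction. A voxel's
position is the position of its centre; indices are 0-based.

Contour planes are perpendicular to the grid's third index axis
(the usual DICOM convention of axial polygons stacked along z); polygon
vertices are (x, y) mm along the first two index axes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely

from .errors import EmptyStructureError, InvalidContourError, OutOfExtentError

_CANONICAL = {"L-R", "R-L", "A-P", "P-A", "I-S", "S-I"}
_AXIS_OF = {"L-R": "LR", "R-L": "LR", "A-P": "AP", "P-A": "AP", "I-S": "IS", "S-I": "IS"}

DEFAULT_AXES = ("L-R", "A-P", "I-S")


@dataclass(frozen=True)
class Grid3D:
    """Regular voxel lattice shared by dose arrays and structure masks.

    Parameters
    ----------
    origin : (3,) float
        Patient-space position (mm) of the centre of voxel (0, 0, 0).
    spacing : (3,) float
        Voxel pitch (mm) along each index axis; strictly positive.
    dims : (3,) int
        Number of voxels along each index axis; at least 1.
    axes : 3-tuple of str
        Anatomical label per index axis, e.g. ``("L-R", "A-P", "I-S")``;
        must name each of the left-right, anterior-posterior and
        inferior-superior directions exactly once.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]
    axes: tuple[str, str, str] = DEFAULT_AXES

    def __post_init__(self):
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))
        object.__setattr__(self, "axes", tuple(self.axes))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.dims) != 3:
            raise ValueError("origin, spacing and dims must each have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be >= 1 per axis, got {self.dims}")
        if any(a not in _CANONICAL for a in self.axes):
            raise ValueError(f"unknown axis label in {self.axes}")
        if sorted(_AXIS_OF[a] for a in self.axes) != ["AP", "IS", "LR"]:
            raise ValueError(f"axes must be a permutation of the three anatomical directions, got {self.axes}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one index axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "spacing": list(self.spacing),
            "dims": list(self.dims),
            "axes": list(self.axes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Grid3D":
        return cls(
            origin=tuple(d["origin"]),
            spacing=tuple(d["spacing"]),
            dims=tuple(d["dims"]),
            axes=tuple(d.get("axes", DEFAULT_AXES)),
        )


@dataclass
class ContourPlane:
    """All closed polygons delineated on one plane at position ``z_mm``."""

    z_mm: float
    polygons: list[np.ndarray]  # each (n, 2) float, implicitly closed

    def __post_init__(self):
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 2 or _n_distinct_vertices(p) < 3:
                raise InvalidContourError(
                    f"polygon on plane z={self.z_mm} has fewer than 3 distinct vertices"
                )


def _n_distinct_vertices(p: np.ndarray) -> int:
    # a trailing repeat of the first vertex (explicit closure) is not distinct
    if len(p) >= 2 and np.allclose(p[0], p[-1]):
        p = p[:-1]
    return len(np.unique(np.round(p, 9), axis=0))


@dataclass
class ContourSet:
    """Planar delineation of one named structure.

    ``planes`` are kept sorted by plane position; polygons are implicitly
    closed (a repeated first vertex is accepted and ignored).
    """

    structure_name: str
    planes: list[ContourPlane] = field(default_factory=list)

    def __post_init__(self):
        self.planes = sorted(self.planes, key=lambda pl: pl.z_mm)
        zs = [pl.z_mm for pl in self.planes]
        if len(set(zs)) != len(zs):
            raise InvalidContourError(f"duplicate plane positions in {self.structure_name}")

    def to_dict(self) -> dict:
        return {
            "structure_name": self.structure_name,
            "planes": [
                {"z_mm": pl.z_mm, "polygons": [p.tolist() for p in pl.polygons]}
                for pl in self.planes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContourSet":
        return cls(
            structure_name=d["structure_name"],
            planes=[ContourPlane(pl["z_mm"], pl["polygons"]) for pl in d["planes"]],
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path: str | Path) -> "ContourSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class StructureMask:
    """Binary voxel occupancy of one named structure on a grid."""

    grid: Grid3D
    occupancy: np.ndarray
    structure_name: str = ""

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != tuple(self.grid.dims):
            raise ValueError(
                f"occupancy shape {self.occupancy.shape} != grid dims {self.grid.dims}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.occupancy.sum())

    def is_empty(self) -> bool:
        return not self.occupancy.any()

    def to_dict(self) -> dict:
        idx = np.argwhere(self.occupancy)
        return {
            "structure_name": self.structure_name,
            "grid": self.grid.to_dict(),
            "voxels": idx.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StructureMask":
        grid = Grid3D.from_dict(d["grid"])
        occ = np.zeros(grid.dims, dtype=bool)
        idx = np.asarray(d["voxels"], dtype=int)
        if idx.size:
            occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return cls(grid=grid, occupancy=occ, structure_name=d.get("structure_name", ""))

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path: str | Path) -> "StructureMask":
        return cls.from_dict(json.loads(Path(path).read_text()))


def rasterize_contours(contours: ContourSet, grid: Grid3D) -> StructureMask:
    """Rasterize planar contours onto a voxel grid.

    A voxel is occupied iff its centre lies inside an odd number of the
    nested polygons of its nearest contour plane (even-odd rule), so holes
    delineated as inner rings are carved out. Each contour plane is mapped
    to the nearest grid slice along the third index axis; ties between two
    equidistant slices resolve to the lower index. Planes without contours
    yield empty slices.

    Raises
    ------
    InvalidContourError
        If any polygon has fewer than 3 distinct vertices.
    OutOfExtentError
        If a contour plane falls outside the grid extent (more than half a
        slice spacing beyond the first or last slice centre).
    """
    occ = np.zeros(grid.dims, dtype=bool)
    z_centers = grid.axis_centers(2)
    half = grid.spacing[2] / 2.0
    xs = grid.axis_centers(0)
    ys = grid.axis_centers(1)
    # voxel-centre coordinate arrays for one slice
    xx, yy = np.meshgrid(xs, ys, indexing="ij")

    for plane in contours.planes:
        if plane.z_mm < z_centers[0] - half or plane.z_mm > z_centers[-1] + half:
            raise OutOfExtentError(
                f"contour plane z={plane.z_mm} mm outside grid extent "
                f"[{z_centers[0] - half}, {z_centers[-1] + half}] mm"
            )
        dist = np.abs(z_centers - plane.z_mm)
        k = int(np.flatnonzero(dist == dist.min())[0])  # tie -> lower index
        inside = np.zeros(xx.shape, dtype=bool)
        for poly in plane.polygons:
            ring = shapely.Polygon(poly)
            if not ring.is_valid or ring.area == 0:
                raise InvalidContourError(
                    f"degenerate polygon on plane z={plane.z_mm} of {contours.structure_name}"
                )
            # strictly-inside containment; XOR over rings implements even-odd
            inside ^= shapely.contains_xy(ring, xx.ravel(), yy.ravel()).reshape(xx.shape)
        occ[:, :, k] |= inside
    return StructureMask(grid=grid, occupancy=occ, structure_name=contours.structure_name)


def resample_mask(mask: StructureMask, target: Grid3D) -> StructureMask:
    """Resample a mask onto another grid by nearest-neighbour assignment.

    Each target voxel centre takes the occupancy of the source voxel whose
    centre is nearest; target centres falling outside the source extent are
    unoccupied. Resampling onto the identical grid is the identity. If the
    grids are spatially disjoint the result is empty and a warning is issued.
    """
    if target == mask.grid:
        return StructureMask(grid=target, occupancy=mask.occupancy.copy(),
                             structure_name=mask.structure_name)
    occ = np.zeros(target.dims, dtype=bool)
    src = mask.grid
    idx_1d = []
    any_overlap = True
    for ax in range(3):
        centers = target.axis_centers(ax)
        i = np.rint((centers - src.origin[ax]) / src.spacing[ax]).astype(int)
        valid = (i >= 0) & (i < src.dims[ax])
        if not valid.any():
            any_overlap = False
        idx_1d.append((i, valid))
    if not any_overlap:
        warnings.warn("resample_mask: source and target grids are spatially disjoint; "
                      "returning an empty mask", stacklevel=2)
        return StructureMask(grid=target, occupancy=occ, structure_name=mask.structure_name)
    i0, v0 = idx_1d[0]
    i1, v1 = idx_1d[1]
    i2, v2 = idx_1d[2]
    valid = v0[:, None, None] & v1[None, :, None] & v2[None, None, :]
    ii = np.clip(i0, 0, src.dims[0] - 1)[:, None, None]
    jj = np.clip(i1, 0, src.dims[1] - 1)[None, :, None]
    kk = np.clip(i2, 0, src.dims[2] - 1)[None, None, :]
    occ = mask.occupancy[ii, jj, kk] & valid
    return StructureMask(grid=target, occupancy=occ, structure_name=mask.structure_name)


def mask_volume(mask: StructureMask) -> float:
    """Structure volume in cc (occupied voxels x voxel volume)."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3 / 1000.0
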