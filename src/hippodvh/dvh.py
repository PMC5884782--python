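"""Dose-volume histograms and the standard organ-at-risk dose metrics.

All doses are stored and reported in cGy. D_x% is the minimum dose received
by the hottest x% of the structure volume, computed from exact voxel-dose
order statistics (rank ``ceil(x/100 * M)`` of the M occupied voxel doses
sorted descending) rather than by interpolating a binned curve, so results
carry no bin-width sensitivity. V_d thresholds are specified in Gy, the
convention of clinical table headers (V_5 means "volume receiving at least
5 Gy" = 500 cGy), and compared with >=: a voxel exactly at the threshold
counts as irradiated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyStructureError, ParameterError
from .structures import StructureMask, mask_volume
from .structures import Grid3D

#: V_n thresholds (Gy) of the standard reporting set
DEFAULT_V_THRESHOLDS_GY = (5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0)


@dataclass
class DoseGrid:
    """Per-voxel absorbed dose (cGy) on a regular grid."""

    grid: Grid3D
    dose: np.ndarray

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != tuple(self.grid.dims):
            raise ValueError(f"dose shape {self.dose.shape} != grid dims {self.grid.dims}")
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative everywhere")


@dataclass
class CumulativeDVH:
    """Cumulative dose-volume histogram.

    ``v_ge[i]`` is the percent of structure volume receiving at least
    ``bin_edges[i]`` cGy; the curve starts at 100% at 0 cGy and is monotone
    non-increasing.
    """

    bin_edges: np.ndarray
    v_ge: np.ndarray
    total_volume_cc: float

    def to_rows(self) -> list[tuple[float, float]]:
        return list(zip(self.bin_edges.tolist(), self.v_ge.tolist()))


@dataclass
class DoseMetrics:
    """The reported metric bundle: D_1%, D_50%, D_99%, D_mean and V_d map."""

    d1: float
    d50: float
    d99: float
    dmean: float
    v_at: dict[float, float] = field(default_factory=dict)  # Gy threshold -> percent


def _masked_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    if dose.grid != mask.grid:
        raise ValueError("mask must be resampled to the dose grid before metric computation")
    if mask.is_empty():
        raise EmptyStructureError(f"structure {mask.structure_name!r} is empty")
    return dose.dose[mask.occupancy]


def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_width: float = 10.0) -> CumulativeDVH:
    """Cumulative DVH of a structure at the given bin width (cGy)."""
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be positive, got {bin_width}")
    d = _masked_doses(dose, mask)
    top = float(d.max())
    n_bins = int(math.ceil(top / bin_width)) + 1 if top > 0 else 1
    edges = np.arange(n_bins + 1) * bin_width
    v_ge = np.array([100.0 * np.count_nonzero(d >= e) / d.size for e in edges])
    return CumulativeDVH(bin_edges=edges, v_ge=v_ge, total_volume_cc=mask_volume(mask))


def dose_at_volume(dose: DoseGrid, mask: StructureMask, x: float) -> float:
    """D_x%: minimum dose (cGy) received by the hottest x% of the volume."""
    if not 0.0 < x <= 100.0:
        raise ParameterError(f"x must lie in (0, 100], got {x}")
    d = np.sort(_masked_doses(dose, mask))[::-1]
    rank = math.ceil(x / 100.0 * d.size)
    return float(d[rank - 1])


def volume_at_dose(dose: DoseGrid, mask: StructureMask, d_cgy: float) -> float:
    """V at a dose threshold: percent of volume receiving >= d_cgy."""
    if d_cgy < 0:
        raise ParameterError(f"dose threshold must be >= 0, got {d_cgy}")
    d = _masked_doses(dose, mask)
    return float(100.0 * np.count_nonzero(d >= d_cgy) / d.size)


def mean_dose(dose: DoseGrid, mask: StructureMask) -> float:
    """D_mean: arithmetic mean of occupied-voxel doses (cGy)."""
    return float(_masked_doses(dose, mask).mean())


def metrics_bundle(
    dose: DoseGrid,
    mask: StructureMask,
    v_thresholds_gy: tuple[float, ...] = DEFAULT_V_THRESHOLDS_GY,
) -> DoseMetrics:
    """D_1%, D_50%, D_99%, D_mean and V at each Gy threshold for one mask."""
    return DoseMetrics(
        d1=dose_at_volume(dose, mask, 1.0),
        d50=dose_at_volume(dose, mask, 50.0),
        d99=dose_at_volume(dose, mask, 99.0),
        dmean=mean_dose(dose, mask),
        v_at={float(t): volume_at_dose(dose, mask, 100.0 * t) for t in v_thresholds_gy},
    )
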