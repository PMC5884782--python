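"""Head/body/tail splitting of a structure along the anterior-posterior axis.

The hippocampus is divided into head, body and tail by fractional layer
counts: the coronal layers the structure spans are counted from the most
anterior to the most posterior occupied slice (span, inclusive), and the
first 35% of layers become the head, the next 45% the body and the final
20% the tail. Layers are assigned whole — no slice is divided between two
sub-regions — with cumulative boundaries rounded half-up so the three
counts always sum to the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyStructureError, OrientationError, TooFewLayersError
from .structures import Grid3D, StructureMask, _AXIS_OF

#: head / body / tail layer fractions
DEFAULT_RATIOS = (0.35, 0.45, 0.20)


@dataclass(frozen=True)
class SubregionRatios:
    """Fractional layer shares of head, body and tail; must sum to 1."""

    f_head: float = DEFAULT_RATIOS[0]
    f_body: float = DEFAULT_RATIOS[1]
    f_tail: float = DEFAULT_RATIOS[2]

    def __post_init__(self):
        for name, f in (("f_head", self.f_head), ("f_body", self.f_body), ("f_tail", self.f_tail)):
            if not 0.0 < f < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {f}")
        if abs(self.f_head + self.f_body + self.f_tail - 1.0) > 1e-9:
            raise ValueError(
                f"ratios must sum to 1, got {self.f_head + self.f_body + self.f_tail}"
            )


@dataclass
class SubregionSplit:
    """Result of splitting a mask into head, body and tail sub-masks.

    ``boundary_slices`` are the grid slice indices of the last head layer
    and the last body layer (in grid index space, before any orientation
    flip); ``n_layers`` is the anterior-posterior span of the parent.
    """

    head: StructureMask
    body: StructureMask
    tail: StructureMask
    boundary_slices: tuple[int, int]
    n_layers: int


def orient_axis(grid: Grid3D) -> tuple[int, bool]:
    """Identify the anterior->posterior index axis of a grid.

    Returns ``(axis, flip)`` where ``axis`` is the grid index axis running
    along the anterior-posterior direction and ``flip`` is True when
    increasing index runs posterior->anterior (label "P-A") so slice order
    must be reversed to scan front-to-back.
    """
    for ax, label in enumerate(grid.axes):
        if _AXIS_OF[label] == "AP":
            return ax, label == "P-A"
    raise OrientationError(
        f"grid axes {grid.axes} do not identify an anterior-posterior direction"
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def count_layers(mask: StructureMask, axis: int | None = None) -> int:
    """Number of coronal layers the structure spans, inclusive.

    The span runs from the first to the last occupied slice along the
    anterior-posterior axis, so interior delineation gaps do not reduce
    the count.
    """
    if mask.is_empty():
        raise EmptyStructureError(f"structure {mask.structure_name!r} is empty")
    if axis is None:
        axis, _ = orient_axis(mask.grid)
    other = tuple(a for a in range(3) if a != axis)
    occupied = np.flatnonzero(mask.occupancy.any(axis=other))
    return int(occupied[-1] - occupied[0] + 1)


def split_structure(
    mask: StructureMask,
    ratios: SubregionRatios | None = None,
    axis: int | None = None,
) -> SubregionSplit:
    """Split a mask into head/body/tail sub-masks by fractional layer count.

    With N span layers indexed 1..N front (anterior) to back, the head
    receives layers 1..c1 and the body layers c1+1..c2, where
    ``c1 = round_half_up(f_head * N)`` and
    ``c2 = round_half_up((f_head + f_body) * N)``; the tail takes the rest.
    Each sub-mask inherits every parent voxel on its layers, so the three
    parts partition the parent exactly.

    Raises
    ------
    EmptyStructureError
        If the mask has no occupied voxel.
    TooFewLayersError
        If the span is below 3 layers (three non-empty parts impossible).
    """
    if ratios is None:
        ratios = SubregionRatios()
    if mask.is_empty():
        raise EmptyStructureError(f"structure {mask.structure_name!r} is empty")
    flip = False
    if axis is None:
        axis, flip = orient_axis(mask.grid)
    other = tuple(a for a in range(3) if a != axis)
    occupied = np.flatnonzero(mask.occupancy.any(axis=other))
    first, last = int(occupied[0]), int(occupied[-1])
    n = last - first + 1
    if n < 3:
        raise TooFewLayersError(
            f"structure {mask.structure_name!r} spans {n} layers; at least 3 required"
        )
    c1 = _round_half_up(ratios.f_head * n)
    c2 = _round_half_up((ratios.f_head + ratios.f_body) * n)
    # guard degenerate roundings so each part keeps >= 1 layer
    c1 = min(max(c1, 1), n - 2)
    c2 = min(max(c2, c1 + 1), n - 1)

    # anterior-most span slice in grid index space
    span = np.arange(first, last + 1)
    if flip:
        span = span[::-1]
    head_slices = span[:c1]
    body_slices = span[c1:c2]
    tail_slices = span[c2:]

    def sub(slices: np.ndarray, suffix: str) -> StructureMask:
        occ = np.zeros_like(mask.occupancy)
        sel = [slice(None)] * 3
        sel[axis] = slices
        occ[tuple(sel)] = mask.occupancy[tuple(sel)]
        return StructureMask(grid=mask.grid, occupancy=occ,
                             structure_name=f"{mask.structure_name}{suffix}")

    return SubregionSplit(
        head=sub(head_slices, "_head"),
        body=sub(body_slices, "_body"),
        tail=sub(tail_slices, "_tail"),
        boundary_slices=(int(head_slices[-1]), int(body_slices[-1])),
        n_layers=n,
    )
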