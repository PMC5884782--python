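"""Shared fixtures: small grids, masks and a reduced phantom configuration."""

import numpy as np
import pytest

from hippodvh import DoseGrid, Grid3D, PhantomConfig, StructureMask


@pytest.fixture
def unit_grid():
    """10x10x10 grid at 1 mm spacing with voxel centres at 0.5 ... 9.5 mm."""
    return Grid3D(origin=(0.5, 0.5, 0.5), spacing=(1, 1, 1), dims=(10, 10, 10))


@pytest.fixture
def small_config():
    """Phantom scaled to a 40x40x30 grid for fast tests."""
    return PhantomConfig(
        grid_dims=(40, 40, 30),
        hc_length_mm=20.0,
        lateral_offset_mm=10.0,
        curvature_mm=4.0,
        source_point_mm=(40.0, 14.0, 10.0),
    )


def random_blob_mask(rng, min_layers=3):
    """Random occupancy on a random small grid; guaranteed >= min_layers span."""
    dims = tuple(int(rng.integers(min_layers + 1, 16)) for _ in range(3))
    spacing = tuple(float(rng.uniform(0.5, 3.5)) for _ in range(3))
    grid = Grid3D(origin=(0, 0, 0), spacing=spacing, dims=dims)
    occ = rng.random(dims) < rng.uniform(0.2, 0.8)
    # force a span of at least min_layers along the A-P axis
    occ[dims[0] // 2, 0, dims[2] // 2] = True
    occ[dims[0] // 2, min_layers - 1, dims[2] // 2] = True
    return StructureMask(grid=grid, occupancy=occ, structure_name="blob")


def uniform_dose(grid: Grid3D, value: float) -> DoseGrid:
    return DoseGrid(grid=grid, dose=np.full(grid.dims, float(value)))


def point_in_polygon(x: float, y: float, poly: np.ndarray) -> bool:
    """Crossing-number (even-odd) point-in-polygon test: independent oracle."""
    inside = False
    n = len(poly)
    j = n - 1
    for i in range(n):
        xi, yi = poly[i]
        xj, yj = poly[j]
        if (yi > y) != (yj > y):
            x_cross = xi + (y - yi) / (yj - yi) * (xj - xi)
            if x < x_cross:
                inside = not inside
        j = i
    return inside
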