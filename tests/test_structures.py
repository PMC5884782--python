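"""Grid, contour and mask behaviour: rasterization, resampling, volumes."""

import numpy as np
import pytest

from hippodvh import (
    ContourPlane,
    ContourSet,
    Grid3D,
    StructureMask,
    mask_volume,
    rasterize_contours,
    resample_mask,
)
from hippodvh.errors import InvalidContourError, OutOfExtentError

from conftest import point_in_polygon

SQUARE = [[0, 0], [10, 0], [10, 10], [0, 10]]


def square_set(z=0.5, polys=(SQUARE,)):
    return ContourSet("sq", [ContourPlane(z, list(polys))])


class TestGrid3D:
    def test_validation_rejects_bad_geometry(self):
        with pytest.raises(ValueError):
            Grid3D(origin=(0, 0, 0), spacing=(1, 0, 1), dims=(5, 5, 5))
        with pytest.raises(ValueError):
            Grid3D(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(5, 0, 5))
        with pytest.raises(ValueError):
            Grid3D(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(5, 5, 5),
                   axes=("L-R", "L-R", "I-S"))

    def test_axis_centers_and_voxel_volume(self):
        g = Grid3D(origin=(1, 2, 3), spacing=(3, 1, 1.5), dims=(2, 3, 4))
        assert g.voxel_volume_mm3 == pytest.approx(4.5)
        np.testing.assert_allclose(g.axis_centers(0), [1, 4])

    def test_dict_round_trip(self):
        g = Grid3D(origin=(0, 0, 0), spacing=(2, 2, 3), dims=(4, 5, 6),
                   axes=("R-L", "A-P", "S-I"))
        assert Grid3D.from_dict(g.to_dict()) == g


class TestRasterize:
    def test_square_fills_all_interior_centers(self, unit_grid):
        mask = rasterize_contours(square_set(), unit_grid)
        assert mask.occupancy[:, :, 0].sum() == 100
        assert mask.n_voxels == 100

    def test_empty_contour_set_gives_empty_mask(self, unit_grid):
        mask = rasterize_contours(ContourSet("none", []), unit_grid)
        assert mask.is_empty()

    def test_triangle_matches_point_in_polygon_oracle(self, unit_grid):
        tri = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        mask = rasterize_contours(ContourSet("tri", [ContourPlane(0.5, [tri])]), unit_grid)
        xs = unit_grid.axis_centers(0)
        ys = unit_grid.axis_centers(1)
        expected = np.array([[point_in_polygon(x, y, tri) for y in ys] for x in xs])
        np.testing.assert_array_equal(mask.occupancy[:, :, 0], expected)

    def test_nested_polygon_carves_hole(self, unit_grid):
        hole = [[3, 3], [7, 3], [7, 7], [3, 7]]
        mask = rasterize_contours(square_set(polys=(SQUARE, hole)), unit_grid)
        assert mask.occupancy[1, 1, 0]  # centre (1.5, 1.5) in outer ring only
        assert not mask.occupancy[5, 5, 0]  # centre (5.5, 5.5) inside the hole
        assert mask.occupancy[:, :, 0].sum() == 100 - 16

    def test_plane_mapped_to_nearest_slice_ties_to_lower(self, unit_grid):
        # z = 1.0 is equidistant between slice centres 0.5 and 1.5 -> slice 0
        mask = rasterize_contours(square_set(z=1.0), unit_grid)
        assert mask.occupancy[:, :, 0].any() and not mask.occupancy[:, :, 1].any()

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(InvalidContourError):
            ContourPlane(0.0, [[[0, 0], [1, 1]]])

    def test_out_of_extent_plane_rejected(self, unit_grid):
        with pytest.raises(OutOfExtentError):
            rasterize_contours(square_set(z=50.0), unit_grid)

    def test_deterministic(self, unit_grid):
        a = rasterize_contours(square_set(), unit_grid)
        b = rasterize_contours(square_set(), unit_grid)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)

    def test_area_converges_with_refinement(self):
        # disc of radius 4 centred at (5, 5); finer grids approximate pi r^2 better
        theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        disc = np.column_stack([5 + 4 * np.cos(theta), 5 + 4 * np.sin(theta)])
        errors = []
        for spacing in (1.0, 0.25):
            n = int(round(10 / spacing))
            g = Grid3D(origin=(spacing / 2, spacing / 2, 0.5), spacing=(spacing, spacing, 1),
                       dims=(n, n, 1))
            m = rasterize_contours(ContourSet("disc", [ContourPlane(0.5, [disc])]), g)
            area = m.n_voxels * spacing ** 2
            errors.append(abs(area - np.pi * 16) / (np.pi * 16))
        assert errors[1] < errors[0]


class TestResample:
    def test_identity_grid_is_identity(self, unit_grid):
        rng = np.random.default_rng(0)
        mask = StructureMask(unit_grid, rng.random(unit_grid.dims) < 0.5, "m")
        out = resample_mask(mask, unit_grid)
        np.testing.assert_array_equal(out.occupancy, mask.occupancy)

    def test_full_mask_onto_subgrid_stays_full(self, unit_grid):
        mask = StructureMask(unit_grid, np.ones(unit_grid.dims, bool), "m")
        sub = Grid3D(origin=(2.5, 2.5, 2.5), spacing=(1, 1, 1), dims=(5, 5, 5))
        assert resample_mask(mask, sub).occupancy.all()

    def test_downsampled_cuboid_volume_preserved(self):
        fine = Grid3D(origin=(0.5, 0.5, 0.5), spacing=(1, 1, 1), dims=(20, 20, 20))
        occ = np.zeros(fine.dims, bool)
        occ[4:16, 4:16, 4:16] = True  # 12 mm cuboid
        mask = StructureMask(fine, occ, "cube")
        coarse = Grid3D(origin=(1.0, 1.0, 1.0), spacing=(2, 2, 2), dims=(10, 10, 10))
        out = resample_mask(mask, coarse)
        # volume preserved within one coarse voxel per boundary face
        assert abs(mask_volume(out) - mask_volume(mask)) <= 1.0
    def test_disjoint_grids_warn_and_empty(self, unit_grid):
        mask = StructureMask(unit_grid, np.ones(unit_grid.dims, bool), "m")
        far = Grid3D(origin=(1000, 1000, 1000), spacing=(1, 1, 1), dims=(5, 5, 5))
        with pytest.warns(UserWarning):
            out = resample_mask(mask, far)
        assert out.is_empty()


class TestVolume:
    @pytest.mark.parametrize("n_vox,spacing,expected_cc", [
        (1000, (1, 1, 1), 1.0),
        (0, (1, 1, 1), 0.0),
        (100, (3, 1, 1.5), 0.45),
    ])
    def test_volume_arithmetic(self, n_vox, spacing, expected_cc):
        g = Grid3D(origin=(0, 0, 0), spacing=spacing, dims=(10, 10, 10))
        occ = np.zeros(1000, bool)
        occ[:n_vox] = True
        assert mask_volume(StructureMask(g, occ.reshape(g.dims), "v")) == pytest.approx(expected_cc)


def test_mask_json_round_trip(unit_grid, tmp_path):
    rng = np.random.default_rng(3)
    mask = StructureMask(unit_grid, rng.random(unit_grid.dims) < 0.3, "rt")
    p = tmp_path / "m.json"
    mask.save_json(p)
    back = StructureMask.load_json(p)
    assert back.structure_name == "rt" and back.grid == unit_grid
    np.testing.assert_array_equal(back.occupancy, mask.occupancy)


def test_contour_json_round_trip(tmp_path):
    cs = square_set()
    p = tmp_path / "c.json"
    cs.save_json(p)
    back = ContourSet.load_json(p)
    assert back.structure_name == "sq"
    np.testing.assert_allclose(back.planes[0].polygons[0], SQUARE)
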