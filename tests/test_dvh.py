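"""DVH curves and D/V metrics against brute-force sort/count oracles."""

import numpy as np
import pytest

from hippodvh import (
    DoseGrid,
    Grid3D,
    StructureMask,
    compute_dvh,
    dose_at_volume,
    mean_dose,
    metrics_bundle,
    volume_at_dose,
)
from hippodvh.errors import EmptyStructureError, ParameterError


def field_on_grid(doses, dims=(10, 10, 1)):
    g = Grid3D(origin=(0, 0, 0), spacing=(1, 1, 1), dims=dims)
    dose = DoseGrid(g, np.asarray(doses, float).reshape(dims))
    mask = StructureMask(g, np.ones(dims, bool), "s")
    return dose, mask


@pytest.fixture
def ramp_1_100():
    """100 equal voxels with doses 1..100 cGy."""
    return field_on_grid(np.arange(1, 101))


class TestComputeDVH:
    def test_uniform_field_is_a_step(self):
        dose, mask = field_on_grid(np.full(100, 1000.0))
        dvh = compute_dvh(dose, mask, bin_width=100)
        assert np.all(dvh.v_ge[dvh.bin_edges <= 1000] == 100.0)
        assert np.all(dvh.v_ge[dvh.bin_edges > 1000] == 0.0)

    def test_two_level_field_half_volume_at_midpoint(self):
        dose, mask = field_on_grid([500.0] * 50 + [1500.0] * 50)
        dvh = compute_dvh(dose, mask, bin_width=10)
        assert dvh.v_ge[dvh.bin_edges == 1000][0] == 50.0

    def test_curve_matches_threshold_counting(self):
        rng = np.random.default_rng(11)
        d = rng.uniform(0, 5000, 100)
        dose, mask = field_on_grid(d)
        dvh = compute_dvh(dose, mask, bin_width=37.0)
        expected = [100.0 * np.count_nonzero(d >= e) / d.size for e in dvh.bin_edges]
        np.testing.assert_allclose(dvh.v_ge, expected)
        assert np.all(np.diff(dvh.v_ge) <= 0)
        assert dvh.v_ge[0] == 100.0

    def test_bad_bin_width_rejected(self):
        dose, mask = field_on_grid(np.ones(100))
        with pytest.raises(ParameterError):
            compute_dvh(dose, mask, bin_width=0)


class TestDoseAtVolume:
    def test_uniform_field_all_percentiles_equal(self):
        dose, mask = field_on_grid(np.full(100, 1000.0))
        for x in (1, 50, 99):
            assert dose_at_volume(dose, mask, x) == 1000.0

    def test_rank_statistic_on_ramp(self, ramp_1_100):
        dose, mask = ramp_1_100
        assert dose_at_volume(dose, mask, 50) == 51.0  # rank 50 descending
        assert dose_at_volume(dose, mask, 100) == 1.0  # minimum
        assert dose_at_volume(dose, mask, 1) == 100.0

    def test_x_out_of_range_rejected(self, ramp_1_100):
        dose, mask = ramp_1_100
        for x in (0, -1, 101):
            with pytest.raises(ParameterError):
                dose_at_volume(dose, mask, x)


class TestVolumeAtDose:
    @pytest.mark.parametrize("threshold,expected", [(500, 100.0), (1500, 0.0), (1000, 100.0)])
    def test_uniform_field(self, threshold, expected):
        dose, mask = field_on_grid(np.full(100, 1000.0))
        assert volume_at_dose(dose, mask, threshold) == expected

    def test_ramp_midpoint(self, ramp_1_100):
        dose, mask = ramp_1_100
        assert volume_at_dose(dose, mask, 50.5) == 50.0

    def test_empty_mask_raises(self):
        dose, _ = field_on_grid(np.ones(100))
        empty = StructureMask(dose.grid, np.zeros(dose.grid.dims, bool), "e")
        with pytest.raises(EmptyStructureError):
            volume_at_dose(dose, empty, 10)


def test_mean_dose_is_arithmetic_mean(ramp_1_100):
    dose, mask = ramp_1_100
    assert mean_dose(dose, mask) == pytest.approx(50.5)


class TestMetricsBundle:
    def test_uniform_field_bundle(self):
        dose, mask = field_on_grid(np.full(100, 1000.0))
        b = metrics_bundle(dose, mask, (5.0, 10.0, 15.0))
        assert b.d1 == b.d50 == b.d99 == b.dmean == 1000.0
        assert b.v_at == {5.0: 100.0, 10.0: 100.0, 15.0: 0.0}

    def test_empty_threshold_list(self, ramp_1_100):
        dose, mask = ramp_1_100
        assert metrics_bundle(dose, mask, ()).v_at == {}

    def test_default_thresholds_are_standard_set(self, ramp_1_100):
        dose, mask = ramp_1_100
        assert set(metrics_bundle(dose, mask).v_at) == {5, 10, 15, 20, 30, 40, 50}


class TestOracleAndInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        dims = tuple(rng.integers(4, 20, 3))
        g = Grid3D(origin=(0, 0, 0), spacing=(1, 1, 2), dims=dims)
        d = rng.uniform(0, 6000, dims)
        occ = rng.random(dims) < 0.5
        occ.flat[0] = True
        dose, mask = DoseGrid(g, d), StructureMask(g, occ, "r")
        vox = np.sort(d[occ])[::-1]
        for x in (1.0, 50.0, 99.0):
            rank = int(np.ceil(x / 100 * vox.size))
            assert dose_at_volume(dose, mask, x) == vox[rank - 1]
        for t in (500.0, 2000.0, 5000.0):
            assert volume_at_dose(dose, mask, t) == 100.0 * (vox >= t).sum() / vox.size
        assert mean_dose(dose, mask) == pytest.approx(vox.sum() / vox.size, rel=1e-9)

    def test_dx_monotone_in_x_and_order_invariants(self):
        rng = np.random.default_rng(2)
        dose, mask = field_on_grid(rng.uniform(0, 4000, 100))
        xs = np.arange(1, 101)
        dx = [dose_at_volume(dose, mask, float(x)) for x in xs]
        assert all(a >= b for a, b in zip(dx, dx[1:]))
        b = metrics_bundle(dose, mask)
        assert b.d1 >= b.d50 >= b.d99
        vox = dose.dose[mask.occupancy]
        assert vox.min() <= b.dmean <= vox.max()

    def test_scaling_covariance(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(0, 3000, 100)
        dose, mask = field_on_grid(raw)
        scaled, _ = field_on_grid(2.5 * raw)
        for x in (1.0, 50.0, 99.0):
            assert dose_at_volume(scaled, mask, x) == pytest.approx(
                2.5 * dose_at_volume(dose, mask, x))
        assert mean_dose(scaled, mask) == pytest.approx(2.5 * mean_dose(dose, mask))
        assert volume_at_dose(scaled, mask, 2.5 * 1000) == volume_at_dose(dose, mask, 1000)

    def test_mismatched_grids_rejected(self, ramp_1_100):
        dose, _ = ramp_1_100
        other = Grid3D(origin=(5, 5, 5), spacing=(1, 1, 1), dims=(10, 10, 1))
        mask = StructureMask(other, np.ones(other.dims, bool), "m")
        with pytest.raises(ValueError):
            mean_dose(dose, mask)
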