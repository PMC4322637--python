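"""Seed generation and probabilistic Euler tracking on synthetic fields."""

import numpy as np
import pytest

from stimdense.grids import LabelVolume, VoxelGrid
from stimdense.streamlines import Streamline
from stimdense.tracking import (
    OrientationField,
    RejectionReason,
    TrackingParams,
    load_orientation_field,
    make_seed_cube,
    save_orientation_field,
    track_all,
    track_streamline,
)


def uniform_field(direction=(1.0, 0.0, 0.0), n=30, spacing=2.0, dispersion=0.0):
    grid = VoxelGrid((0.0, 0.0, 0.0), (spacing,) * 3, (n, n, n))
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    directions = np.zeros(grid.shape + (2, 3))
    directions[..., 0, :] = d
    fractions = np.zeros(grid.shape + (2,))
    fractions[..., 0] = 1.0
    dispersion_deg = np.full(grid.shape, float(dispersion))
    return OrientationField(grid, directions, fractions, dispersion_deg)


class TestSeedCube:
    def test_standard_cube_has_1331_seeds_spanning_22mm(self):
        seeds = make_seed_cube(np.array([10.0, 20.0, 30.0]), 11, 2.0)
        assert len(seeds) == 1331
        assert np.allclose(seeds.max(axis=0) - seeds.min(axis=0), 20.0)  # centers
        # voxel extent including the half-voxel on each side = 22 mm
        assert 20.0 + 2.0 == 22.0

    def test_single_voxel_cube(self):
        seeds = make_seed_cube(np.array([1.0, 2.0, 3.0]), 1, 2.0)
        assert seeds.shape == (1, 3)
        assert np.allclose(seeds[0], [1, 2, 3])

    def test_edge3_enumeration(self):
        center = np.array([0.0, 0.0, 0.0])
        seeds = make_seed_cube(center, 3, 1.0)
        assert len(seeds) == 27
        assert np.allclose(seeds.min(axis=0), -1.0)
        assert np.allclose(seeds.max(axis=0), 1.0)
        expected = {
            (i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        }
        assert {tuple(s) for s in seeds} == expected

    def test_even_edge_rejected(self):
        with pytest.raises(ValueError):
            make_seed_cube(np.zeros(3), 4, 2.0)


class TestTrackStreamline:
    def test_uniform_field_gives_straight_line(self):
        field = uniform_field()
        p = TrackingParams(max_steps=25, samples_per_seed=1, rng_seed=1)
        rng = np.random.default_rng(0)
        s = track_streamline(np.array([30.0, 30.0, 30.0]), field, p, rng)
        assert isinstance(s, Streamline)
        # both halves run to the field boundary or the step cap
        seg = np.diff(s.points, axis=0)
        assert np.allclose(np.linalg.norm(seg, axis=1), 0.5, atol=1e-9)
        assert np.allclose(s.points[:, 1], 30.0)
        assert np.allclose(s.points[:, 2], 30.0)
        # 25 steps each way from the seed
        assert len(s.points) == 2 * 25 + 1

    def test_abrupt_turn_terminates_at_curvature_gate(self):
        field = uniform_field()
        # make x >= 30 mm voxels point along +y: a 90 degree wall
        half = field.directions[..., 0, :].copy()
        half[15:, :, :] = [0.0, 1.0, 0.0]
        field.directions[..., 0, :] = half
        p = TrackingParams(curvature_deg=80.0, max_steps=100, rng_seed=1)
        rng = np.random.default_rng(0)
        s = track_streamline(np.array([10.0, 30.0, 30.0]), field, p, rng)
        # the +x half stops at the wall instead of turning 90 degrees
        assert s.points[:, 0].max() <= 31.0

    def test_circular_arc_field_follows_analytic_circle(self):
        """Oracle: a tangential direction field around a circle of radius 20."""
        n, spacing = 40, 1.0
        grid = VoxelGrid((-20.0, -20.0, -2.0), (spacing,) * 3, (n, n, 4))
        centers = np.stack(
            np.meshgrid(*[grid.cell_centers_axis(a) for a in range(3)], indexing="ij"),
            axis=-1,
        )
        xy = centers[..., :2]
        radial = np.linalg.norm(xy, axis=-1, keepdims=True)
        radial_dir = np.where(radial > 1e-9, xy / radial, 0.0)
        tangent = np.stack(
            [-radial_dir[..., 1], radial_dir[..., 0], np.zeros_like(radial_dir[..., 0])],
            axis=-1,
        )
        directions = np.zeros(grid.shape + (2, 3))
        directions[..., 0, :] = tangent
        fractions = np.zeros(grid.shape + (2,))
        fractions[..., 0] = 1.0
        field = OrientationField(grid, directions, fractions, np.zeros(grid.shape))

        radius = 15.0
        p = TrackingParams(max_steps=40, rng_seed=3, loop_check=False)
        rng = np.random.default_rng(0)
        s = track_streamline(np.array([radius, 0.0, 0.5]), field, p, rng)
        arc = np.linalg.norm(np.diff(s.points, axis=0), axis=1).sum()
        assert arc >= 20.0
        radii = np.linalg.norm(s.points[:, :2], axis=1)
        assert np.max(np.abs(radii - radius)) < 2 * p.step_mm

    def test_seed_in_termination_mask_rejected(self):
        field = uniform_field()
        mask_vals = np.ones(field.grid.shape, dtype=np.int32)
        mask = LabelVolume(field.grid, mask_vals, {1: "csf"})
        p = TrackingParams(termination_mask=mask)
        rng = np.random.default_rng(0)
        out = track_streamline(np.array([30.0, 30.0, 30.0]), field, p, rng)
        assert out is RejectionReason.SEED_IN_TERMINATION_MASK

    def test_seed_out_of_bounds_rejected(self):
        field = uniform_field()
        rng = np.random.default_rng(0)
        out = track_streamline(np.array([-5.0, 0.0, 0.0]), field, TrackingParams(), rng)
        assert out is RejectionReason.SEED_OUT_OF_BOUNDS


class TestTrackAll:
    def test_count_conservation_and_shapes(self):
        field = uniform_field(dispersion=5.0)
        p = TrackingParams(max_steps=30, samples_per_seed=3, rng_seed=11)
        seeds = make_seed_cube(np.array([30.0, 30.0, 30.0]), 3, 2.0)
        out, rejections = track_all(seeds, field, p)
        assert len(out) + len(rejections) == len(seeds) * p.samples_per_seed

    def test_deterministic_under_fixed_seed(self):
        field = uniform_field(dispersion=10.0)
        p = TrackingParams(max_steps=30, samples_per_seed=2, rng_seed=42)
        seeds = make_seed_cube(np.array([30.0, 30.0, 30.0]), 3, 2.0)
        a, _ = track_all(seeds, field, p)
        b, _ = track_all(seeds, field, p)
        assert len(a) == len(b)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.points, s2.points)

    def test_uniform_field_shapes_are_identical(self):
        field = uniform_field()
        p = TrackingParams(max_steps=20, samples_per_seed=3, rng_seed=0)
        seeds = np.tile(np.array([[30.0, 30.0, 30.0]]), (10, 1))
        out, _ = track_all(seeds, field, p)
        assert len(out) == 30
        ref = out[0].points - out[0].points[0]
        for s in out:
            assert np.allclose(s.points - s.points[0], ref)


class TestTrackingInvariants:
    @pytest.fixture
    def tracked(self):
        field = uniform_field(direction=(1.0, 0.3, -0.2), dispersion=15.0)
        p = TrackingParams(max_steps=50, samples_per_seed=5, rng_seed=5)
        seeds = make_seed_cube(np.array([30.0, 30.0, 30.0]), 3, 2.0)
        out, _ = track_all(seeds, field, p)
        return out, p

    def test_step_length_exact(self, tracked):
        out, p = tracked
        for s in out:
            seg = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
            assert np.max(np.abs(seg - p.step_mm)) < 1e-6

    def test_turning_angles_within_curvature_gate(self, tracked):
        out, p = tracked
        for s in out:
            seg = np.diff(s.points, axis=0)
            seg = seg / np.linalg.norm(seg, axis=1, keepdims=True)
            cosang = np.clip(np.sum(seg[:-1] * seg[1:], axis=1), -1, 1)
            angles = np.degrees(np.arccos(cosang))
            assert np.all(angles <= p.curvature_deg + 1e-6)

    def test_point_count_bounded(self, tracked):
        out, p = tracked
        for s in out:
            assert len(s.points) <= 2 * p.max_steps + 1


def test_orientation_field_round_trip(tmp_path):
    field = uniform_field(direction=(0.0, 1.0, 0.0), n=8, dispersion=7.5)
    save_orientation_field(tmp_path / "orient", field)
    back = load_orientation_field(tmp_path / "orient")
    assert back.grid == field.grid
    assert np.allclose(back.directions, field.directions)
    assert np.allclose(back.fractions, field.fractions)
    assert np.allclose(back.dispersion_deg, field.dispersion_deg)
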