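"""Myelinated-axon cable model: construction, dynamics, and classification."""

import numpy as np
import pytest

from stimdense.axon import (
    NOT_ACTIVATABLE,
    ActivationResult,
    SimulationConfig,
    activating_function,
    build_axon,
    classify_fibers,
    extracellular_potentials,
    find_threshold,
    is_active,
    load_membrane_parameters,
    resting_potential,
    simulate_response,
)
from stimdense.field import StimulusWaveform, waveform_samples
from stimdense.grids import ScalarVolume, VoxelGrid
from stimdense.streamlines import FiberTooShortError, Streamline, StreamlineSet


def straight(length_mm, y=0.0, z=0.0, n=None):
    n = n or int(length_mm * 10) + 1
    x = np.linspace(0.0, length_mm, n)
    return Streamline(np.column_stack([x, np.full(n, y), np.full(n, z)]))


def point_source_volume(center, v_contact=-0.87, r_c=0.8, extent=60.0, spacing=1.0):
    """Analytic 1/r cathodic potential sampled on a grid (clamped at r_c)."""
    n = int(extent / spacing)
    grid = VoxelGrid((0.0, 0.0, 0.0), (spacing,) * 3, (n, n, n))
    centers = np.stack(
        np.meshgrid(*[grid.cell_centers_axis(a) for a in range(3)], indexing="ij"),
        axis=-1,
    )
    r = np.linalg.norm(centers - np.asarray(center), axis=-1)
    vals = v_contact * r_c / np.maximum(r, r_c)
    return ScalarVolume(grid, vals)


def unit_ve(axon, source, cfg, pulse_width=60.0, r_c=0.8):
    """Extracellular mV drive per volt of cathodic amplitude (1/r field)."""
    w = StimulusWaveform(pulse_width=pulse_width)
    _, wave = waveform_samples(w, cfg.dt)
    wave = wave[: cfg.n_steps]
    r = np.linalg.norm(axon.positions - np.asarray(source), axis=1)
    phi = -1e3 * r_c / np.maximum(r, r_c)
    return phi[:, None] * wave[None, :]


class TestBuildAxon:
    def test_10mm_fiber_has_21_nodes(self, membrane_params):
        a = build_axon(straight(10.0), params=membrane_params)
        assert a.n_nodes == 21

    def test_25mm_fiber_has_51_nodes_at_half_mm(self, membrane_params):
        a = build_axon(straight(25.0), params=membrane_params)
        assert a.n_nodes == 51
        spacing = np.linalg.norm(np.diff(a.node_positions, axis=0), axis=1)
        assert np.max(np.abs(spacing - 0.5)) < 1e-6

    def test_too_short_fiber_is_excluded_not_classified(self, membrane_params):
        with pytest.raises(FiberTooShortError):
            build_axon(straight(8.0), params=membrane_params)

    def test_curved_fiber_nodes_match_dense_resampling_oracle(self, membrane_params):
        t = np.linspace(0, np.pi, 400)
        radius = 10.0
        pts = np.column_stack([radius * np.cos(t), radius * np.sin(t), 0.1 * t])
        s = Streamline(pts)
        a = build_axon(s, params=membrane_params)
        # oracle: walk the polyline at 0.1 um resolution
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        dense_arcs = np.arange(0, cum[-1] + 1e-12, 1e-4)
        dense = np.column_stack(
            [np.interp(dense_arcs, cum, pts[:, k]) for k in range(3)]
        )
        oracle = dense[:: 5000][: a.n_nodes]  # every 0.5 mm
        assert np.max(np.linalg.norm(a.node_positions - oracle, axis=1)) < 2e-3

    def test_compartment_layout_per_section(self, membrane_params):
        a = build_axon(straight(10.0), params=membrane_params)
        # node + paranode + internode + paranode per section, final node extra
        assert a.n_comp == 4 * (a.n_nodes - 1) + 1
        assert np.all(a.capacitance > 0)
        assert np.all(a.g_axial > 0)

    def test_resting_potential_is_hyperpolarized_and_stable(self, membrane_params):
        v = resting_potential(membrane_params)
        assert -95.0 < v < -75.0


class TestSimulateResponse:
    def test_resting_state_is_stable(self, straight_axon):
        cfg = SimulationConfig(duration=3000.0)
        ve = np.zeros((straight_axon.n_comp, cfg.n_steps))
        traces = simulate_response(straight_axon, ve, cfg)
        assert np.max(np.abs(traces - straight_axon.v_rest)) < 1.0
        assert not is_active(traces, cfg)

    def test_central_injection_propagates_to_both_ends(self, straight_axon):
        cfg = SimulationConfig()
        ve = np.zeros((straight_axon.n_comp, cfg.n_steps))
        inj = np.zeros_like(ve)
        center = straight_axon.node_index[straight_axon.n_nodes // 2]
        inj[center, :50] = 0.01  # 10 nA for 100 us
        traces = simulate_response(straight_axon, ve, cfg, i_inject=inj)
        assert is_active(traces, cfg)
        assert traces[0].max() > 20.0 and traces[-1].max() > 20.0

    def test_extracellular_linearity(self, straight_axon):
        cfg = SimulationConfig(duration=200.0)
        vol = point_source_volume((15.0, 3.0, 0.0))
        w = StimulusWaveform()
        ve1 = extracellular_potentials(straight_axon, vol, w, cfg.dt, duration=200.0)
        doubled = point_source_volume((15.0, 3.0, 0.0), v_contact=-1.74)
        ve2 = extracellular_potentials(straight_axon, doubled, w, cfg.dt, duration=200.0)
        assert np.allclose(ve2, 2.0 * ve1, atol=1e-9)

    def test_zero_field_gives_zero_ve(self, straight_axon):
        grid = VoxelGrid((0.0, 0.0, 0.0), (1.0,) * 3, (40, 40, 40))
        vol = ScalarVolume(grid, np.zeros(grid.shape))
        ve = extracellular_potentials(
            straight_axon, vol, StimulusWaveform(), 2.0, duration=100.0
        )
        assert np.all(ve == 0.0)

    def test_grid_node_sampling_identity(self, membrane_params, rng):
        """A compartment placed at a voxel center sees the stored value."""
        grid = VoxelGrid((0.0, 0.0, 0.0), (1.0,) * 3, (40, 40, 40))
        vol = ScalarVolume(grid, rng.normal(size=grid.shape))
        axon = build_axon(straight(12.0, y=9.5, z=9.5), params=membrane_params)
        w = StimulusWaveform()
        ve = extracellular_potentials(axon, vol, w, 2.0, duration=60.0)
        # node 1 (compartment 4) sits at (0.5, 9.5, 9.5) = center of voxel (0, 9, 9)
        assert np.allclose(axon.positions[4], [0.5, 9.5, 9.5])
        expected = 1e3 * vol.values[0, 9, 9]
        assert ve[4, 0] == pytest.approx(expected, rel=1e-9)


class TestIsActive:
    def test_flat_traces_inactive(self):
        cfg = SimulationConfig()
        traces = np.full((5, 100), -80.0)
        assert not is_active(traces, cfg)

    def test_single_ended_crossing_is_not_propagation(self):
        cfg = SimulationConfig()
        traces = np.full((5, 100), -80.0)
        traces[0, 50:] = 20.0  # local response at one end only
        assert not is_active(traces, cfg)

    def test_both_ends_crossing_is_active(self):
        cfg = SimulationConfig()
        traces = np.full((5, 100), -80.0)
        traces[0, 50:60] = 20.0
        traces[-1, 70:80] = 20.0
        assert is_active(traces, cfg)


class TestFindThreshold:
    def test_threshold_monotone_in_distance(self, straight_axon):
        cfg = SimulationConfig()
        thresholds = [
            find_threshold(
                straight_axon, unit_ve(straight_axon, (15.0, d, 0.0), cfg), cfg,
                tol_v=0.02,
            )
            for d in (2.0, 3.0, 5.0)
        ]
        assert thresholds[0] < thresholds[1] < thresholds[2]

    def test_strength_duration_monotone_in_pulse_width(self, straight_axon):
        cfg = SimulationConfig()
        thr_60 = find_threshold(
            straight_axon, unit_ve(straight_axon, (15.0, 2.0, 0.0), cfg, 60.0), cfg,
            tol_v=0.01,
        )
        thr_120 = find_threshold(
            straight_axon, unit_ve(straight_axon, (15.0, 2.0, 0.0), cfg, 120.0), cfg,
            tol_v=0.01,
        )
        assert thr_120 <= thr_60

    def test_bracket_respects_tolerance(self, straight_axon):
        cfg = SimulationConfig()
        ve = unit_ve(straight_axon, (15.0, 2.0, 0.0), cfg)
        coarse = find_threshold(straight_axon, ve, cfg, tol_v=0.05)
        fine = find_threshold(straight_axon, ve, cfg, tol_v=0.001)
        assert abs(coarse - fine) <= 0.05 + 1e-9

    def test_unreachable_fiber_returns_sentinel(self, straight_axon):
        cfg = SimulationConfig()
        ve = unit_ve(straight_axon, (15.0, 45.0, 0.0), cfg)  # 45 mm away
        assert find_threshold(straight_axon, ve, cfg, max_amplitude=1.0) == NOT_ACTIVATABLE


class TestClassifyFibers:
    def near_far_set(self):
        fibers = StreamlineSet()
        for i in range(10):  # near: 2 mm lateral to the source
            fibers.append(straight(30.0, y=32.0, z=28.0 + 0.1 * i))
        for i in range(10):  # far: ~17 mm away
            fibers.append(straight(30.0, y=47.0, z=28.0 + 0.1 * i))
        return fibers

    def test_zero_field_activates_nothing(self, membrane_params):
        grid = VoxelGrid((0.0, 0.0, 0.0), (2.0,) * 3, (20, 20, 20))
        vol = ScalarVolume(grid, np.zeros(grid.shape))
        result = classify_fibers(
            self.near_far_set(), vol, StimulusWaveform(), params=membrane_params
        )
        assert result.n_active == 0

    def test_only_near_fibers_activate_at_calibrated_amplitude(self, membrane_params):
        vol = point_source_volume((15.0, 30.0, 30.0), v_contact=-0.87)
        result = classify_fibers(
            self.near_far_set(), vol, StimulusWaveform(), params=membrane_params
        )
        assert result.active[:10] == [True] * 10
        assert result.active[10:] == [False] * 10

    def test_order_invariance_and_conservation(self, membrane_params):
        vol = point_source_volume((15.0, 30.0, 30.0), v_contact=-0.87)
        fibers = self.near_far_set()
        fibers.append(straight(5.0, y=32.0, z=40.0))  # too short: excluded
        fwd = classify_fibers(fibers, vol, StimulusWaveform(), params=membrane_params)
        assert fwd.n_classified + len(fwd.excluded) == len(fibers)
        assert len(fwd.excluded) == 1
        rev = StreamlineSet(list(fibers)[::-1])
        bwd = classify_fibers(rev, vol, StimulusWaveform(), params=membrane_params)
        assert sorted(fwd.active) == sorted(bwd.active)
        assert bwd.n_active == fwd.n_active


class TestActivatingFunction:
    def test_peaks_at_node_nearest_cathode(self, straight_axon):
        vol = point_source_volume((15.0, 2.0, 0.0))
        f = activating_function(straight_axon, vol)
        # cathodic source: the second difference is maximal near x = 15
        # (voxel-center interpolation can shift the discrete peak by ~1 cell)
        peak_node = int(np.argmax(f))
        assert abs(straight_axon.node_positions[peak_node][0] - 15.0) <= 2.0
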