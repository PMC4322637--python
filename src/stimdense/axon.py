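"""Multi-compartment myelinated axon models driven by the DBS field.

Each tracked streamline that is long enough is turned into a cable model with
nodes of Ranvier every 0.5 mm (5.7 um fiber parameter set by default) and
simulated under the extracellular potential sampled from the solved voltage
volume.  A fiber is classified *active* when the stimulus elicits an action
potential that propagates to BOTH fiber ends (an upward crossing of the
detection threshold at both terminal nodes).

The membrane model is an MRG-style reduction: per 0.5 mm section one node,
two flanking paranodes and one lumped internode; nodes carry fast Na+,
persistent Na+, slow K+ and leak conductances (36 C kinetics), myelinated
compartments are passive with myelin-attenuated capacitance.  Integration is
a backward-Euler step on the cable equation (axial currents computed from
Vi = Vm + Ve) with Rush-Larsen exponential gate updates, which is
unconditionally stable.

Internal units: mV, ms, uF, mS (so uF * mV/ms = uA and mS * mV = uA).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from .field import StimulusWaveform, waveform_samples
from .grids import ScalarVolume
from .streamlines import FiberTooShortError, Streamline, StreamlineSet, resample_streamline

__all__ = [
    "load_membrane_parameters",
    "AxonModel",
    "SimulationConfig",
    "ActivationResult",
    "build_axon",
    "extracellular_potentials",
    "simulate_response",
    "is_active",
    "find_threshold",
    "classify_fibers",
    "activating_function",
    "IntegrationError",
    "NOT_ACTIVATABLE",
]

UM_TO_CM = 1e-4
MM_TO_CM = 0.1

NODE, PARA, INTER = 0, 1, 2  # compartment kinds

NOT_ACTIVATABLE = float("inf")
"""Sentinel returned by :func:`find_threshold` when no amplitude activates."""


class IntegrationError(RuntimeError):
    """Membrane potential left the physical range (numerical blow-up)."""


def load_membrane_parameters(name: str = "mrg_5p7um_v1") -> dict:
    """Load a named membrane/geometry parameter table shipped with the package."""
    ref = importlib.resources.files("stimdense") / "data" / f"{name}.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


# -- MRG node kinetics (36 C) ----------------------------------------------------


def _vtrap(x: np.ndarray, num: float, den: float) -> np.ndarray:
    """num * x / (1 - exp(-x/den)) with the removable singularity handled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-7
    safe = np.where(small, 1.0, x)
    out = num * safe / (1.0 - np.exp(-safe / den))
    return np.where(small, num * den, out)


def _gate_rates(v: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """(alpha, beta) in 1/ms for gates m, h, p, s at membrane potential v (mV).

    Potentials are clipped to [-250, 250] mV: the rates saturate there anyway
    and the clip keeps exponentials finite when strong fields polarize
    compartments far outside the physiological range.
    """
    v = np.clip(np.asarray(v, dtype=float), -250.0, 250.0)
    am = _vtrap(v + 20.4, 6.57, 10.3)
    bm = _vtrap(-(v + 25.7), 0.304, 9.16)
    ah = _vtrap(-(v + 114.0), 0.34, 11.0)
    bh = 12.6 / (1.0 + np.exp(-(v + 31.8) / 13.4))
    ap = _vtrap(v + 27.0, 0.0353, 10.2)
    bp = _vtrap(-(v + 34.0), 0.000883, 10.0)
    as_ = 0.3 / (1.0 + np.exp(-(v + 53.0) / 5.0))
    bs = 0.03 / (1.0 + np.exp(-(v + 90.0) / 1.0))
    return {"m": (am, bm), "h": (ah, bh), "p": (ap, bp), "s": (as_, bs)}


def _steady_gates(v: float) -> dict[str, float]:
    rates = _gate_rates(np.asarray(v))
    return {k: float(a / (a + b)) for k, (a, b) in rates.items()}


def _node_current_density(v: float, params: dict) -> float:
    """Steady-state ionic current density at a node (uA/cm^2); 0 at rest."""
    el = params["electrical"]["node"]
    g = _steady_gates(v)
    i_naf = el["g_naf_S_per_cm2"] * g["m"] ** 3 * g["h"] * (v - el["e_na_mV"])
    i_nap = el["g_nap_S_per_cm2"] * g["p"] ** 3 * (v - el["e_na_mV"])
    i_ks = el["g_ks_S_per_cm2"] * g["s"] * (v - el["e_k_mV"])
    i_lk = el["g_leak_S_per_cm2"] * (v - el["e_leak_mV"])
    return 1e3 * (i_naf + i_nap + i_ks + i_lk)  # S/cm^2 * mV = mA/cm^2 -> uA/cm^2


def resting_potential(params: dict) -> float:
    """Node resting potential: the most hyperpolarized *stable* zero of the
    steady-state ionic current (negative-to-positive crossing) in [-100, -60] mV.

    The fitted node kinetics admit several equilibria; the hyperpolarized
    stable one is the physiological rest.
    """
    vv = np.linspace(-100.0, -60.0, 401)
    ii = np.array([_node_current_density(float(v), params) for v in vv])
    crossings = np.flatnonzero((ii[:-1] < 0) & (ii[1:] >= 0))
    if len(crossings) == 0:
        raise ValueError("no stable resting potential found in [-100, -60] mV")
    k = crossings[0]
    return brentq(lambda v: _node_current_density(v, params), vv[k], vv[k + 1], xtol=1e-9)


# -- cable construction ----------------------------------------------------------


@dataclass
class AxonModel:
    """Compartmentalized myelinated cable built on a resampled streamline.

    ``kinds`` marks each compartment as node / paranode / internode;
    ``positions`` are world-mm compartment centers; electrical vectors are in
    the internal uF / mS unit system.
    """

    node_positions: np.ndarray        # (n_nodes, 3) world mm
    positions: np.ndarray             # (n_comp, 3) world mm
    kinds: np.ndarray                 # (n_comp,) int
    capacitance: np.ndarray           # (n_comp,) uF
    g_axial: np.ndarray               # (n_comp - 1,) mS, between neighbors
    areas: np.ndarray                 # (n_comp,) cm^2
    v_rest: float                     # mV
    params: dict = dc_field(default_factory=dict, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_positions)

    @property
    def n_comp(self) -> int:
        return len(self.positions)

    @property
    def node_index(self) -> np.ndarray:
        return np.flatnonzero(self.kinds == NODE)


def _polyline_interp(points: np.ndarray, arcs: np.ndarray) -> np.ndarray:
    """Points on a polyline at given arc lengths."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return np.column_stack([np.interp(arcs, cum, points[:, k]) for k in range(3)])


def build_axon(
    s: Streamline,
    params: dict | None = None,
    min_nodes: int = 21,
) -> AxonModel:
    """Instantiate the cable model on a streamline.

    Nodes of Ranvier are placed at 0.5 mm arc-length intervals starting at the
    first point; fibers supporting fewer than ``min_nodes`` nodes raise
    :class:`~stimdense.streamlines.FiberTooShortError` (they are *excluded*,
    not classified inactive).
    """
    if params is None:
        params = load_membrane_parameters()
    geo = params["geometry"]
    el = params["electrical"]
    internode_mm = params["internodal_distance_um"] * 1e-3

    resampled = resample_streamline(s, internode_mm)
    node_positions = resampled.points
    n_nodes = len(node_positions)
    if n_nodes < min_nodes:
        raise FiberTooShortError(
            f"{n_nodes} nodes < minimum {min_nodes} (arc length {s.arc_length:.2f} mm)"
        )

    L_node = geo["node_length_um"] * 1e-3       # mm
    L_para = geo["paranode_length_um"] * 1e-3
    L_inter = internode_mm - L_node - 2 * L_para
    if L_inter <= 0:
        raise ValueError("internodal distance too short for compartment layout")

    # per-section compartment arc offsets (centers), relative to the node arc
    offsets = np.array([
        0.0,                                    # node (centered on the node arc)
        0.5 * L_node + 0.5 * L_para,            # paranode 1
        0.5 * L_node + L_para + 0.5 * L_inter,  # internode
        internode_mm - 0.5 * L_node - 0.5 * L_para,  # paranode 2
    ])
    arcs: list[float] = []
    kinds: list[int] = []
    for i in range(n_nodes - 1):
        base = i * internode_mm
        arcs.extend(base + offsets)
        kinds.extend([NODE, PARA, INTER, PARA])
    arcs.append((n_nodes - 1) * internode_mm)
    kinds.append(NODE)
    arcs_arr = np.asarray(arcs)
    kinds_arr = np.asarray(kinds, dtype=int)
    positions = _polyline_interp(s.points, np.minimum(arcs_arr, _arc_total(s)))

    lengths_cm = np.where(
        kinds_arr == NODE, L_node,
        np.where(kinds_arr == PARA, L_para, L_inter),
    ) * MM_TO_CM
    diams_cm = np.where(
        kinds_arr == NODE, geo["node_diameter_um"],
        np.where(kinds_arr == PARA, geo["paranode_diameter_um"], geo["internode_diameter_um"]),
    ) * UM_TO_CM
    areas = np.pi * diams_cm * lengths_cm       # cm^2, lateral
    cm = np.where(
        kinds_arr == NODE,
        el["node"]["cm_uF_per_cm2"],
        el["myelinated"]["cm_uF_per_cm2"],
    )
    capacitance = cm * areas                    # uF

    rho = el["axial_resistivity_ohm_cm"]        # Ohm*cm
    half_r = 4.0 * rho * (0.5 * lengths_cm) / (np.pi * diams_cm**2)  # Ohm
    r_link = half_r[:-1] + half_r[1:]
    g_axial = 1e3 / r_link                      # mS

    v_rest = resting_potential(params)
    return AxonModel(
        node_positions=node_positions,
        positions=positions,
        kinds=kinds_arr,
        capacitance=capacitance,
        g_axial=g_axial,
        areas=areas,
        v_rest=v_rest,
        params=params,
    )


def _arc_total(s: Streamline) -> float:
    return float(np.linalg.norm(np.diff(s.points, axis=0), axis=1).sum())


# -- simulation ------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings for the cable simulation."""

    dt: float = 2.0                 # us
    duration: float = 3000.0        # us
    detection_threshold: float = 0.0  # mV, upward crossing
    min_nodes: int = 21
    integrator: str = "backward_euler_rush_larsen"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


def extracellular_potentials(
    a: AxonModel,
    v: ScalarVolume,
    w: StimulusWaveform,
    dt: float,
    duration: float | None = None,
    mode: str = "square",
) -> np.ndarray:
    """Extracellular potential Ve(compartment, t) in mV at sample interval dt (us).

    Ve is the trilinear sample of the voltage volume at each compartment
    center, modulated by the unit-amplitude stimulus waveform; compartments
    outside the volume see Ve = 0.  The result is linear in the stimulus
    amplitude baked into ``v``.
    """
    spatial = np.asarray(v.sample_trilinear(a.positions, outside=0.0), dtype=float)
    _, wave = waveform_samples(w, dt, mode=mode)
    if duration is not None:
        n = int(round(duration / dt))
        if n <= len(wave):
            wave = wave[:n]
        else:
            reps = int(np.ceil(n / len(wave)))
            wave = np.tile(wave, reps)[:n]
    return 1e3 * spatial[:, None] * wave[None, :]  # V -> mV


def simulate_response(
    a: AxonModel,
    ve: np.ndarray,
    cfg: SimulationConfig,
    i_inject: np.ndarray | None = None,
) -> np.ndarray:
    """Integrate the cable equation; returns Vm traces (mV) at the nodes.

    ``ve`` is (n_comp, n_t) in mV; ``i_inject`` optionally adds an
    intracellular current (uA) of the same shape.  The scheme: Rush-Larsen
    exponential update of the node gates at the current potential, then one
    backward-Euler solve of the (tridiagonal) linear cable system with the
    updated conductances frozen.  Output shape is (n_nodes, n_t + 1) and
    includes the initial resting sample.
    """
    el = a.params["electrical"]["node"]
    node_idx = a.node_index
    n = a.n_comp
    n_t = ve.shape[1]
    dt_ms = cfg.dt * 1e-3

    v = np.full(n, a.v_rest)
    gates = {k: np.full(len(node_idx), g) for k, g in _steady_gates(a.v_rest).items()}

    area_n = a.areas[node_idx]
    g_naf_max = el["g_naf_S_per_cm2"] * area_n * 1e3   # mS
    g_nap_max = el["g_nap_S_per_cm2"] * area_n * 1e3
    g_ks_max = el["g_ks_S_per_cm2"] * area_n * 1e3
    g_leak = el["g_leak_S_per_cm2"] * area_n * 1e3
    e_na, e_k, e_l = el["e_na_mV"], el["e_k_mV"], el["e_leak_mV"]

    pas_mask = a.kinds != NODE
    g_pas = np.zeros(n)
    g_pas[pas_mask] = (
        a.params["electrical"]["myelinated"]["g_pas_S_per_cm2"] * a.areas[pas_mask] * 1e3
    )
    e_pas = a.v_rest  # passive reversal pinned to rest: uniform rest is stationary

    gax = a.g_axial
    lap_diag = np.zeros(n)
    lap_diag[:-1] += gax
    lap_diag[1:] += gax
    c_dt = a.capacitance / dt_ms

    # banded template: rows (upper, diag, lower) for solve_banded
    ab = np.zeros((3, n))
    ab[0, 1:] = -gax
    ab[2, :-1] = -gax

    out = np.empty((len(node_idx), n_t + 1))
    out[:, 0] = a.v_rest

    # Strong fields legitimately polarize compartments by a fraction of the
    # local Ve differences, so the blow-up guard scales with the drive.
    blow_up_mv = 500.0 + 1.2 * (np.max(np.abs(ve)) if ve.size else 0.0)

    for t in range(n_t):
        vn = v[node_idx]
        rates = _gate_rates(vn)
        for k, (al, be) in rates.items():
            tau = 1.0 / (al + be)
            inf = al * tau
            gates[k] = inf + (gates[k] - inf) * np.exp(-dt_ms / tau)

        g_na = g_naf_max * gates["m"] ** 3 * gates["h"]
        g_np = g_nap_max * gates["p"] ** 3
        g_k = g_ks_max * gates["s"]
        g_ion = np.array(g_pas)
        ion_drive = g_pas * e_pas
        g_ion[node_idx] = g_na + g_np + g_k + g_leak
        ion_drive[node_idx] = (g_na + g_np) * e_na + g_k * e_k + g_leak * e_l

        rhs = c_dt * v + ion_drive
        ve_t = ve[:, t]
        rhs[:-1] += gax * (ve_t[1:] - ve_t[:-1])
        rhs[1:] += gax * (ve_t[:-1] - ve_t[1:])
        if i_inject is not None:
            rhs += i_inject[:, t]

        ab[1, :] = c_dt + g_ion + lap_diag
        v = solve_banded((1, 1), ab, rhs)
        if np.max(np.abs(v)) > blow_up_mv:
            raise IntegrationError(
                f"|Vm| exceeded {blow_up_mv:.0f} mV at step {t} (dt={cfg.dt} us)"
            )
        out[:, t + 1] = v[node_idx]
    return out


def is_active(traces: np.ndarray, cfg: SimulationConfig) -> bool:
    """Propagating-AP criterion: threshold crossed upward at BOTH terminal nodes."""
    thr = cfg.detection_threshold

    def crossed(trace: np.ndarray) -> bool:
        return bool(np.any((trace[:-1] < thr) & (trace[1:] >= thr)))

    return crossed(traces[0]) and crossed(traces[-1])


def activating_function(a: AxonModel, v: ScalarVolume) -> np.ndarray:
    """Second spatial difference of the extracellular potential at the nodes (mV).

    A fast pre-screen for likely activation sites (large positive values
    depolarize); final classification always uses the cable simulation.
    """
    ve = 1e3 * np.asarray(v.sample_trilinear(a.node_positions, outside=0.0))
    f = np.zeros_like(ve)
    f[1:-1] = ve[2:] - 2 * ve[1:-1] + ve[:-2]
    return f


def _simulate_at_amplitude(
    a: AxonModel,
    ve_unit: np.ndarray,
    amplitude: float,
    cfg: SimulationConfig,
) -> bool:
    traces = simulate_response(a, amplitude * ve_unit, cfg)
    return is_active(traces, cfg)


def find_threshold(
    a: AxonModel,
    ve_unit: np.ndarray,
    cfg: SimulationConfig | None = None,
    tol_v: float = 0.01,
    max_amplitude: float = 10.0,
) -> float:
    """Bisect the activation threshold amplitude (V, magnitude) for a fiber.

    ``ve_unit`` is the extracellular potential per 1 V of (cathodic) stimulus
    amplitude, so the field is solved once and scaled (linearity of the
    Poisson problem).  Returns :data:`NOT_ACTIVATABLE` if ``max_amplitude``
    does not activate; otherwise the bracket width is <= ``tol_v``.
    """
    cfg = cfg or SimulationConfig()
    # Ladder up from a small amplitude: very strong fields can block
    # conduction (hyperpolarizing surround), so the active set is an interval
    # and the *lowest* activating amplitude is the threshold sought.
    lo, hi = 0.0, None
    amp = max(tol_v, 0.01)
    while amp <= max_amplitude:
        if _simulate_at_amplitude(a, ve_unit, amp, cfg):
            hi = amp
            break
        lo = amp
        amp *= 1.6
    if hi is None:
        if amp / 1.6 < max_amplitude and _simulate_at_amplitude(
            a, ve_unit, max_amplitude, cfg
        ):
            lo, hi = amp / 1.6, max_amplitude
        else:
            return NOT_ACTIVATABLE
    while hi - lo > tol_v:
        mid = 0.5 * (lo + hi)
        if _simulate_at_amplitude(a, ve_unit, mid, cfg):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class ActivationResult:
    """Per-fiber activation flags plus excluded (too-short) fibers."""

    active: list[bool]
    fiber_ids: list[int]
    node_positions: list[np.ndarray]
    excluded: list[tuple[int, str]]

    @property
    def n_active(self) -> int:
        return int(sum(self.active))

    @property
    def n_classified(self) -> int:
        return len(self.active)

    def active_node_positions(self) -> list[np.ndarray]:
        return [p for p, a in zip(self.node_positions, self.active) if a]

    def to_frame(self):
        import pandas as pd

        rows = [
            {"fiber_id": fid, "active": act, "n_nodes": len(pos), "excluded_reason": ""}
            for fid, act, pos in zip(self.fiber_ids, self.active, self.node_positions)
        ]
        rows += [
            {"fiber_id": fid, "active": False, "n_nodes": 0, "excluded_reason": reason}
            for fid, reason in self.excluded
        ]
        columns = ["fiber_id", "active", "n_nodes", "excluded_reason"]
        frame = pd.DataFrame(rows, columns=columns)
        return frame.sort_values("fiber_id").reset_index(drop=True)


def classify_fibers(
    fibers: StreamlineSet,
    v: ScalarVolume,
    w: StimulusWaveform,
    cfg: SimulationConfig | None = None,
    params: dict | None = None,
    waveform_mode: str = "square",
) -> ActivationResult:
    """Classify every eligible fiber as active/inactive under the solved field.

    Too-short fibers (< ``cfg.min_nodes`` nodes) are excluded with a reason
    and do not appear among the classified flags; excluded + classified
    always equals the number of input fibers.
    """
    cfg = cfg or SimulationConfig()
    if params is None:
        params = load_membrane_parameters()
    active: list[bool] = []
    fiber_ids: list[int] = []
    node_positions: list[np.ndarray] = []
    excluded: list[tuple[int, str]] = []
    for i, s in enumerate(fibers):
        try:
            axon = build_axon(s, params=params, min_nodes=cfg.min_nodes)
        except FiberTooShortError as exc:
            excluded.append((i, str(exc)))
            continue
        ve = extracellular_potentials(
            axon, v, w, cfg.dt, duration=cfg.duration, mode=waveform_mode
        )
        traces = simulate_response(axon, ve, cfg)
        active.append(is_active(traces, cfg))
        fiber_ids.append(i)
        node_positions.append(axon.node_positions)
    return ActivationResult(
        active=active,
        fiber_ids=fiber_ids,
        node_positions=node_positions,
        excluded=excluded,
    )
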