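"""DBS extracellular field: electrode geometry, stimulus, and the Poisson solve.

The voltage distribution produced by monopolar cathodic stimulation is
obtained by solving the quasi-static Poisson equation

    div( sigma grad V ) = 0

on a regular grid with an anisotropic conductivity tensor ``sigma`` per voxel,
Dirichlet ``v_eff`` on voxels intersecting the active contact surface,
Dirichlet 0 on the outer box (distant monopolar return), and an effectively
insulating lead shaft (near-zero conductivity inside non-contact lead voxels).
The electrode-tissue interface is represented quasi-statically: a fixed
fraction of the programmed amplitude (default 42%) is dropped across the
interface and encapsulation, so the contact is driven at
``v_eff = amplitude * (1 - drop_fraction)``; an RC-filtered waveform mode is
available for sensitivity checks.

Conductivities are in S/mm throughout (1 S/m = 1e-3 S/mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grids import GridError, ScalarVolume, TensorVolume, VoxelGrid

__all__ = [
    "ElectrodeModel",
    "StimulusWaveform",
    "ConductivityVolume",
    "contact_surface_area",
    "diffusion_to_conductivity",
    "effective_contact_voltage",
    "point_source_potential",
    "waveform_samples",
    "solve_poisson_fd",
    "FieldSolveError",
]

S_PER_M_TO_S_PER_MM = 1e-3

#: Tuch et al. linear diffusivity-to-conductivity scaling, S*s/mm^2.
DEFAULT_TUCH_SCALE = 0.844


class FieldSolveError(RuntimeError):
    """Linear solve for the voltage distribution failed to converge."""


@dataclass(frozen=True)
class ElectrodeModel:
    """Quadripolar cylindrical DBS lead (Medtronic 3389 geometry by default).

    Four vertically aligned contacts of 1.5 mm length separated by 0.5 mm
    gaps on a 1.27 mm diameter shaft.  Contact 0 is the most distal (closest
    to the tip); ``tip_position`` is the world coordinate of the lead tip and
    ``axis`` points from tip towards the connector.
    """

    tip_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    active_contact: int = 0
    n_contacts: int = 4
    contact_length: float = 1.5
    contact_gap: float = 0.5
    lead_diameter: float = 1.27
    tip_offset: float = 1.5  # insulated tip length below contact 0

    def __post_init__(self) -> None:
        if self.contact_length < 0 or self.lead_diameter <= 0 or self.contact_gap < 0:
            raise ValueError("electrode dimensions must be positive")
        if not (0 <= self.active_contact < self.n_contacts):
            raise ValueError(
                f"active_contact must be in 0..{self.n_contacts - 1}, "
                f"got {self.active_contact}"
            )
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0:
            raise ValueError("electrode axis must be non-zero")
        object.__setattr__(self, "axis", tuple(float(v) for v in ax / n))
        object.__setattr__(self, "tip_position", tuple(float(v) for v in self.tip_position))

    def contact_span(self, contact: int) -> tuple[float, float]:
        """Axial [start, end] of a contact, mm from the tip."""
        start = self.tip_offset + contact * (self.contact_length + self.contact_gap)
        return start, start + self.contact_length

    def contact_center(self, contact: int | None = None) -> np.ndarray:
        """World position of a contact's axial midpoint (active one by default)."""
        c = self.active_contact if contact is None else contact
        lo, hi = self.contact_span(c)
        return np.asarray(self.tip_position) + 0.5 * (lo + hi) * np.asarray(self.axis)


def contact_surface_area(e: ElectrodeModel) -> float:
    """Lateral (cylindrical) surface area of one contact in mm^2.

    For the standard 1.27 mm x 1.5 mm contact this is ~5.98 mm^2.
    """
    if e.lead_diameter <= 0 or e.contact_length < 0:
        raise ValueError("non-positive electrode dimensions")
    return float(np.pi * e.lead_diameter * e.contact_length)


@dataclass(frozen=True)
class StimulusWaveform:
    """Monopolar voltage-controlled pulse train.

    Cathodic amplitudes are negative.  Interface capacitance and impedance
    parameterize the optional RC-filtered waveform mode.
    """

    amplitude: float = -1.5          # V
    pulse_width: float = 60.0        # us
    frequency: float = 130.0         # Hz
    interface_capacitance: float = 3.3  # uF
    impedance: float = 1000.0        # Ohm

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if self.pulse_width <= 0 or self.frequency <= 0:
            raise ValueError("pulse width and frequency must be positive")
        if self.pulse_width * self.frequency >= 1e6:
            raise ValueError("duty cycle must be < 100% (pulse_width * frequency < 1e6)")

    @property
    def period_us(self) -> float:
        return 1e6 / self.frequency

    @property
    def tau_us(self) -> float:
        """Interface RC time constant in microseconds."""
        return self.impedance * self.interface_capacitance  # Ohm * uF = us


def effective_contact_voltage(w: StimulusWaveform, drop_fraction: float = 0.42) -> float:
    """Contact voltage after the electrode-interface/encapsulation drop.

    A ``drop_fraction`` of 0.42 with a -1.5 V amplitude delivers -0.87 V to
    the tissue.
    """
    if not (0.0 <= drop_fraction < 1.0):
        raise ValueError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
    return w.amplitude * (1.0 - drop_fraction)


def waveform_samples(
    w: StimulusWaveform, dt: float, mode: str = "square"
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude stimulus scaling factors over one pulse period.

    Parameters
    ----------
    dt : float
        Sample interval in microseconds; must satisfy ``dt <= pulse_width/6``.
    mode : {'square', 'rc_filtered'}
        ``square``: 1 during [0, pulse_width), 0 elsewhere.
        ``rc_filtered``: periodic steady-state response of an RC high-pass
        (tau = impedance * capacitance) to the square train; its mean over a
        period is zero (capacitive charge balance).

    Returns
    -------
    (t, y) : arrays of sample times (us) and scaling factors.
    """
    if dt > w.pulse_width / 6:
        raise ValueError(f"dt={dt} us too coarse; need dt <= pulse_width/6")
    n = int(round(w.period_us / dt))
    t = np.arange(n) * dt
    square = (t < w.pulse_width).astype(float)
    if mode == "square":
        return t, square
    if mode == "rc_filtered":
        # periodic steady state via the exact transfer function H = j*w*tau/(1+j*w*tau)
        freqs = np.fft.rfftfreq(n, d=dt)  # cycles per us
        jwt = 1j * 2 * np.pi * freqs * w.tau_us
        h = jwt / (1.0 + jwt)
        y = np.fft.irfft(np.fft.rfft(square) * h, n=n)
        return t, y
    raise ValueError(f"unknown waveform mode {mode!r}")


@dataclass
class ConductivityVolume:
    """Anisotropic tissue conductivity (S/mm) plus encapsulation parameters."""

    tensors: TensorVolume
    encapsulation_conductivity: float = 0.128 * S_PER_M_TO_S_PER_MM  # S/mm
    encapsulation_thickness: float = 0.5  # mm

    def __post_init__(self) -> None:
        if self.encapsulation_conductivity <= 0:
            raise ValueError("encapsulation conductivity must be positive")

    @property
    def grid(self) -> VoxelGrid:
        return self.tensors.grid


def diffusion_to_conductivity(
    d: TensorVolume,
    scale: float = DEFAULT_TUCH_SCALE,
    eig_tol: float = 1e-9,
    **encaps,
) -> ConductivityVolume:
    """Linear diffusivity-to-conductivity transform: sigma = scale * D per voxel.

    The map is elementwise on the tensor, so eigenvectors are preserved and
    eigenvalues scale by ``scale`` (S*s/mm^2; diffusivities in mm^2/s yield
    S/mm).  Voxels with an all-zero tensor are legal and behave as
    non-conducting.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    vals = np.asarray(d.values, dtype=float)
    eigvals = np.linalg.eigvalsh(vals.reshape(-1, 3, 3))
    if eigvals.min() < -eig_tol:
        raise GridError(
            f"diffusion tensor has negative eigenvalue {eigvals.min():g}"
        )
    sigma = TensorVolume(d.grid, scale * vals)
    return ConductivityVolume(sigma, **encaps)


def point_source_potential(current: float, sigma_iso: float, r) -> np.ndarray | float:
    """Closed-form monopole potential V = I / (4 pi sigma r) in infinite medium.

    ``current`` in A, ``sigma_iso`` in S/mm, ``r`` in mm -> V in volts.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if sigma_iso <= 0:
        raise ValueError("sigma_iso must be positive")
    out = current / (4.0 * np.pi * sigma_iso * r)
    return float(out) if out.ndim == 0 else out


# -- electrode voxelization ------------------------------------------------------


def _lead_masks(
    sigma: ConductivityVolume, e: ElectrodeModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(contact, shaft, encapsulation) boolean voxel masks on the sigma grid."""
    grid = sigma.grid
    centers = np.stack(
        np.meshgrid(*[grid.cell_centers_axis(a) for a in range(3)], indexing="ij"),
        axis=-1,
    )
    rel = centers - np.asarray(e.tip_position)
    ax = np.asarray(e.axis)
    axial = rel @ ax                       # signed distance along lead axis from tip
    radial = np.linalg.norm(rel - axial[..., None] * ax, axis=-1)
    lead_r = e.lead_diameter / 2.0
    # half-voxel dilation so a sub-voxel-diameter lead still occupies voxels
    halfvox = 0.5 * float(np.max(grid.spacing))
    in_radius = radial <= lead_r + halfvox
    lead_len = e.contact_span(e.n_contacts - 1)[1] + 1.0
    in_shaft_axial = (axial >= -halfvox) & (axial <= lead_len + halfvox)
    lo, hi = e.contact_span(e.active_contact)
    in_contact_axial = (axial >= lo - halfvox) & (axial <= hi + halfvox)
    contact = in_radius & in_contact_axial
    shaft = in_radius & in_shaft_axial & ~contact
    encaps = (
        (radial <= lead_r + sigma.encapsulation_thickness + halfvox)
        & in_shaft_axial
        & ~contact
        & ~shaft
    )
    if not contact.any():
        raise GridError("active contact does not intersect the conductivity grid")
    return contact, shaft, encaps


def solve_poisson_fd(
    sigma: ConductivityVolume,
    e: ElectrodeModel,
    v_eff: float,
    min_margin_voxels: int = 10,
    rtol: float = 1e-10,
) -> ScalarVolume:
    """Finite-difference solve of div(sigma grad V) = 0 on the conductivity grid.

    Boundary conditions: Dirichlet ``v_eff`` on voxels intersecting the active
    contact, Dirichlet 0 on the outer box faces, insulating lead shaft
    (conductivity ~0 inside non-contact lead voxels so no normal flux enters),
    and encapsulation-sheath conductivity in a shell of
    ``encapsulation_thickness`` around the lead.

    The anisotropic divergence form is discretized conservatively: diagonal
    tensor entries with harmonic face averaging give the 7-point stencil;
    off-diagonal entries add central-difference cross terms.

    Raises
    ------
    FieldSolveError
        If the linear solve's relative residual exceeds ``rtol`` * source norm.
    """
    grid = sigma.grid
    contact, shaft, encaps = _lead_masks(sigma, e)
    center = e.contact_center()
    lo_margin = (center - grid.extent[0]) / np.asarray(grid.spacing)
    hi_margin = (grid.extent[1] - center) / np.asarray(grid.spacing)
    if min(lo_margin.min(), hi_margin.min()) < min_margin_voxels:
        raise GridError(
            f"active contact needs >= {min_margin_voxels} voxels margin to the grid boundary"
        )

    if v_eff == 0.0:
        return ScalarVolume(grid, np.zeros(grid.shape))

    tensors = np.array(sigma.tensors.values, copy=True)
    iso = np.eye(3)
    tensors[encaps] = sigma.encapsulation_conductivity * iso
    tensors[shaft] = 1e-12 * iso  # insulating shaft: (near-)zero flux
    tensors[contact] = np.mean(
        np.trace(sigma.tensors.values[~shaft & ~contact], axis1=-2, axis2=-1) / 3.0
    ) * iso  # contact interior conducts like average tissue; value is irrelevant (Dirichlet)

    nx, ny, nz = grid.shape
    n = nx * ny * nz
    h = np.asarray(grid.spacing)

    def lin(i, j, k):
        return (i * ny + j) * nz + k

    idx = np.arange(n).reshape(grid.shape)

    boundary = np.zeros(grid.shape, dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    fixed = boundary | contact
    fixed_vals = np.zeros(grid.shape)
    fixed_vals[contact] = v_eff

    diag = np.zeros(n)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    data: list[np.ndarray] = []
    rhs = np.zeros(n)

    sig_d = np.stack([tensors[..., a, a] for a in range(3)], axis=-1)  # diagonal entries

    def add_entries(r, c, v):
        rows.append(r.ravel())
        cols.append(c.ravel())
        data.append(v.ravel())

    # diagonal-part fluxes: 7-point stencil with harmonic face averaging
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        s_lo = sig_d[tuple(sl_lo)][..., axis]
        s_hi = sig_d[tuple(sl_hi)][..., axis]
        with np.errstate(divide="ignore", invalid="ignore"):
            face = np.where(s_lo + s_hi > 0, 2.0 * s_lo * s_hi / (s_lo + s_hi), 0.0)
        w = face / h[axis] ** 2
        i_lo = idx[tuple(sl_lo)]
        i_hi = idx[tuple(sl_hi)]
        np.add.at(diag, i_lo.ravel(), w.ravel())
        np.add.at(diag, i_hi.ravel(), w.ravel())
        add_entries(i_lo, i_hi, -w)
        add_entries(i_hi, i_lo, -w)

    has_offdiag = bool(
        np.any(np.abs(tensors[..., 0, 1]) > 1e-15)
        or np.any(np.abs(tensors[..., 0, 2]) > 1e-15)
        or np.any(np.abs(tensors[..., 1, 2]) > 1e-15)
    )
    if has_offdiag:
        # d/dxi ( s_ij dV/dxj ), i != j, central differences on interior points
        for ai in range(3):
            for aj in range(3):
                if ai == aj:
                    continue
                s_ij = tensors[..., ai, aj]
                interior = np.zeros(grid.shape, dtype=bool)
                core = [slice(1, -1)] * 3
                interior[tuple(core)] = True
                ii, jj, kk = np.nonzero(interior)
                step_i = np.zeros(3, dtype=int)
                step_j = np.zeros(3, dtype=int)
                step_i[ai] = 1
                step_j[aj] = 1
                coeff = 1.0 / (4.0 * h[ai] * h[aj])
                for si in (+1, -1):
                    ni_, nj_, nk_ = ii + si * step_i[0], jj + si * step_i[1], kk + si * step_i[2]
                    s_shift = s_ij[ni_, nj_, nk_]
                    for sj in (+1, -1):
                        mi = ni_ + sj * step_j[0]
                        mj = nj_ + sj * step_j[1]
                        mk = nk_ + sj * step_j[2]
                        ok = (
                            (mi >= 0) & (mi < nx)
                            & (mj >= 0) & (mj < ny)
                            & (mk >= 0) & (mk < nz)
                        )
                        v = -(si * sj) * coeff * s_shift[ok]
                        add_entries(
                            idx[ii[ok], jj[ok], kk[ok]],
                            idx[mi[ok], mj[ok], mk[ok]],
                            v,
                        )

    rows_a = np.concatenate(rows + [np.arange(n)])
    cols_a = np.concatenate(cols + [np.arange(n)])
    data_a = np.concatenate(data + [diag])
    A = sp.csr_matrix((data_a, (rows_a, cols_a)), shape=(n, n))

    # impose Dirichlet rows: move known columns to RHS, identity on fixed rows
    fixed_flat = fixed.ravel()
    xfix = np.zeros(n)
    xfix[fixed_flat] = fixed_vals.ravel()[fixed_flat]
    rhs = -A @ xfix
    rhs[fixed_flat] = xfix[fixed_flat]

    free = ~fixed_flat
    A_ff = A[free][:, free].tocsc()
    b_f = rhs[free]

    x = np.array(xfix)
    if A_ff.shape[0] > 0:
        n_free = A_ff.shape[0]
        if n_free <= 120_000 or has_offdiag:
            try:
                solve = spla.factorized(A_ff)
                x_f = solve(b_f)
            except RuntimeError as exc:
                raise FieldSolveError(f"sparse factorization failed: {exc}") from exc
        else:
            m = spla.LinearOperator(
                A_ff.shape, matvec=lambda v, d=A_ff.diagonal(): v / d
            )
            x_f, info = spla.cg(A_ff, b_f, rtol=1e-12, maxiter=20000, M=m)
            if info != 0:
                raise FieldSolveError(f"CG failed to converge (info={info})")
        res = np.linalg.norm(A_ff @ x_f - b_f)
        src = np.linalg.norm(b_f)
        if src > 0 and res > max(rtol * src, 1e-14):
            raise FieldSolveError(
                f"linear solve residual {res:g} exceeds {rtol:g} of source norm {src:g}"
            )
        x[free] = x_f

    return ScalarVolume(grid, x.reshape(grid.shape))
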