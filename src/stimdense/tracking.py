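"""Probabilistic streamline tracking around the active contact.

The tracker follows probtrackX-style conventions: a cubic seed region centered
on the active contact, Euler integration at a fixed 0.5 mm step, per-voxel
direction sampling from up to two fiber populations (weighted by volume
fraction, sign-aligned with the incoming direction, with Gaussian angular
jitter), a +/-80 degree curvature gate, termination on a CSF mask, loop
detection, and a step cap.  Tracking runs in both directions from the seed
and the two halves are concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from enum import Enum

import numpy as np

from .grids import LabelVolume, VoxelGrid, world_to_cell
from .streamlines import Streamline, StreamlineSet

__all__ = [
    "OrientationField",
    "TrackingParams",
    "RejectionReason",
    "make_seed_cube",
    "track_streamline",
    "track_all",
]


class RejectionReason(str, Enum):
    SEED_OUT_OF_BOUNDS = "seed_out_of_bounds"
    SEED_IN_TERMINATION_MASK = "seed_in_termination_mask"
    SEED_NO_DIRECTION = "seed_no_direction"
    TOO_SHORT = "too_short"


@dataclass
class OrientationField:
    """Per-voxel fiber directions: up to 2 unit vectors with fractions and dispersion.

    ``directions`` has shape (nx, ny, nz, 2, 3); unused populations have zero
    fraction.  ``dispersion_deg`` is the Gaussian angular jitter (degrees)
    applied when sampling a direction in that voxel.
    """

    grid: VoxelGrid
    directions: np.ndarray
    fractions: np.ndarray
    dispersion_deg: np.ndarray

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.dispersion_deg = np.asarray(self.dispersion_deg, dtype=float)
        shp = self.grid.shape
        if self.directions.shape != shp + (2, 3):
            raise ValueError(f"directions must be {shp + (2, 3)}, got {self.directions.shape}")
        if self.fractions.shape != shp + (2,):
            raise ValueError(f"fractions must be {shp + (2,)}, got {self.fractions.shape}")
        if self.dispersion_deg.shape != shp:
            raise ValueError(f"dispersion must be {shp}, got {self.dispersion_deg.shape}")
        if np.any(self.fractions < 0) or np.any(self.fractions.sum(axis=-1) > 1 + 1e-9):
            raise ValueError("fractions must be >= 0 and sum to <= 1 per voxel")
        norms = np.linalg.norm(self.directions, axis=-1)
        active = self.fractions > 0
        if np.any(np.abs(norms[active] - 1.0) > 1e-6):
            raise ValueError("directions with nonzero fraction must be unit vectors")


@dataclass
class TrackingParams:
    """probtrackX-style tracking parameters."""

    step_mm: float = 0.5
    curvature_deg: float = 80.0
    max_steps: int = 2000
    samples_per_seed: int = 100
    termination_mask: LabelVolume | None = None
    loop_check: bool = True
    loop_limit: int = 2   # terminate on entering a voxel for the (loop_limit+1)-th time
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not (0 < self.curvature_deg < 180):
            raise ValueError("curvature_deg must be in (0, 180)")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


def save_orientation_field(directory, field: OrientationField) -> None:
    """Write an orientation field as paired NIfTI volumes in a directory.

    Files: ``dir1.nii``/``dir2.nii`` (4D, last axis xyz components),
    ``fractions.nii`` (4D, 2 populations), ``dispersion.nii`` (3D, degrees).
    """
    import nibabel as nib
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = field.grid.to_affine()
    nib.save(nib.Nifti1Image(field.directions[..., 0, :], aff), directory / "dir1.nii")
    nib.save(nib.Nifti1Image(field.directions[..., 1, :], aff), directory / "dir2.nii")
    nib.save(nib.Nifti1Image(field.fractions, aff), directory / "fractions.nii")
    nib.save(nib.Nifti1Image(field.dispersion_deg, aff), directory / "dispersion.nii")


def load_orientation_field(directory) -> OrientationField:
    """Read an orientation field written by :func:`save_orientation_field`."""
    import nibabel as nib
    from pathlib import Path

    from .grids import VoxelGrid as _VG

    directory = Path(directory)
    d1 = nib.load(str(directory / "dir1.nii"))
    grid = _VG.from_affine(d1.affine, d1.shape[:3])
    d1a = np.asarray(d1.dataobj)
    d2a = np.asarray(nib.load(str(directory / "dir2.nii")).dataobj)
    frac = np.asarray(nib.load(str(directory / "fractions.nii")).dataobj)
    disp = np.asarray(nib.load(str(directory / "dispersion.nii")).dataobj)
    return OrientationField(
        grid=grid,
        directions=np.stack([d1a, d2a], axis=-2),
        fractions=frac,
        dispersion_deg=disp,
    )


def make_seed_cube(
    center: np.ndarray, edge_voxels: int = 11, voxel_mm: float = 2.0
) -> np.ndarray:
    """Voxel-center seed points of an odd cube centered on ``center``.

    The standard configuration (edge 11, voxel 2 mm) gives 1331 seeds spanning
    a 22 mm cube centered on the active-contact midpoint.
    """
    if edge_voxels % 2 == 0 or edge_voxels < 1:
        raise ValueError(f"edge_voxels must be odd and >= 1, got {edge_voxels}")
    if voxel_mm <= 0:
        raise ValueError(f"voxel_mm must be positive, got {voxel_mm}")
    half = edge_voxels // 2
    offsets = (np.arange(edge_voxels) - half) * voxel_mm
    gx, gy, gz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    return np.asarray(center, dtype=float) + pts


def _sample_direction(
    field: OrientationField,
    cell: tuple[int, int, int],
    prev_dir: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Draw a propagation direction in a voxel, or None if no population there."""
    frac = field.fractions[cell]
    total = frac.sum()
    if total <= 0:
        return None
    pick = 0 if frac.shape[0] == 1 else int(rng.random() * total > frac[0])
    d = np.array(field.directions[cell][pick])
    if prev_dir is not None and np.dot(d, prev_dir) < 0:
        d = -d  # fiber orientations are sign-ambiguous; align with travel
    disp = np.deg2rad(field.dispersion_deg[cell])
    if disp > 0:
        d = _jitter(d, disp, rng)
    return d


def _jitter(d: np.ndarray, disp_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate d by a Gaussian polar angle about a uniform azimuth."""
    theta = abs(rng.normal(0.0, disp_rad))
    phi = rng.uniform(0.0, 2 * np.pi)
    # orthonormal basis around d
    a = np.array([1.0, 0.0, 0.0])
    if abs(d[0]) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, a)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    out = (
        np.cos(theta) * d
        + np.sin(theta) * (np.cos(phi) * u + np.sin(phi) * v)
    )
    return out / np.linalg.norm(out)


def _in_mask(mask: LabelVolume | None, point: np.ndarray) -> bool:
    if mask is None:
        return False
    cell = world_to_cell(point, mask.grid)
    if cell == (-1, -1, -1):
        return False
    return bool(mask.values[cell] != 0)


def _track_half(
    seed: np.ndarray,
    init_dir: np.ndarray,
    field: OrientationField,
    p: TrackingParams,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Euler-integrate one direction from the seed; returns points after the seed."""
    cos_gate = np.cos(np.deg2rad(p.curvature_deg))
    pos = np.array(seed, dtype=float)
    direction = np.array(init_dir, dtype=float)
    pts: list[np.ndarray] = []
    visits: dict[tuple[int, int, int], int] = {}
    last_cell = world_to_cell(seed, field.grid)
    for _ in range(p.max_steps):
        nxt = pos + p.step_mm * direction
        cell = world_to_cell(nxt, field.grid)
        if cell == (-1, -1, -1):
            break
        if _in_mask(p.termination_mask, nxt):
            break
        if p.loop_check and cell != last_cell:
            # count voxel *entries*: several sub-voxel steps are one visit
            visits[cell] = visits.get(cell, 0) + 1
            if visits[cell] > p.loop_limit:
                break
        last_cell = cell
        pts.append(nxt)
        pos = nxt
        new_dir = _sample_direction(field, cell, direction, rng)
        if new_dir is None:
            break
        if np.dot(new_dir, direction) < cos_gate:
            break
        direction = new_dir
    return pts


def track_streamline(
    seed: np.ndarray,
    field: OrientationField,
    p: TrackingParams,
    rng: np.random.Generator,
    seed_index: int = -1,
) -> Streamline | RejectionReason:
    """Track one bidirectional streamline from a seed point.

    Returns a :class:`~stimdense.streamlines.Streamline` or a
    :class:`RejectionReason` when the seed itself is unusable or the result is
    degenerate (fewer than 2 points).
    """
    seed = np.asarray(seed, dtype=float)
    cell = world_to_cell(seed, field.grid)
    if cell == (-1, -1, -1):
        return RejectionReason.SEED_OUT_OF_BOUNDS
    if _in_mask(p.termination_mask, seed):
        return RejectionReason.SEED_IN_TERMINATION_MASK
    d0 = _sample_direction(field, cell, None, rng)
    if d0 is None:
        return RejectionReason.SEED_NO_DIRECTION
    fwd = _track_half(seed, d0, field, p, rng)
    bwd = _track_half(seed, -d0, field, p, rng)
    pts = list(reversed(bwd)) + [seed] + fwd
    if len(pts) < 2:
        return RejectionReason.TOO_SHORT
    return Streamline(np.asarray(pts), seed_index=seed_index)


def track_all(
    seeds: np.ndarray, field: OrientationField, p: TrackingParams
) -> tuple[StreamlineSet, list[tuple[int, RejectionReason]]]:
    """Track ``samples_per_seed`` streamlines per seed, deterministically.

    Returns the streamline set plus a log of ``(seed_index, reason)``
    rejections; ``len(set) + len(rejections) == len(seeds) * samples_per_seed``.
    """
    rng = np.random.default_rng(p.rng_seed)
    out = StreamlineSet()
    rejections: list[tuple[int, RejectionReason]] = []
    for i, seed in enumerate(np.atleast_2d(np.asarray(seeds, dtype=float))):
        for _ in range(p.samples_per_seed):
            res = track_streamline(seed, field, p, rng, seed_index=i)
            if isinstance(res, RejectionReason):
                rejections.append((i, res))
            else:
                out.append(res)
    return out, rejections
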