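"""Axis-aligned voxel grids and volume containers.

All coordinates are world millimetres.  A :class:`VoxelGrid` is axis-aligned:
``origin`` is the world coordinate of the *corner* of voxel ``(0, 0, 0)`` and
cells are half-open intervals ``[origin + i*spacing, origin + (i+1)*spacing)``
per axis, so every in-bounds point maps to exactly one cell.  Voxel *centers*
sit at ``origin + (i + 0.5) * spacing``; the NIfTI affine we read and write
uses the center convention, and the corner/center translation happens only at
the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "ScalarVolume",
    "TensorVolume",
    "LabelVolume",
    "world_to_cell",
    "read_volume",
    "write_volume",
    "GridError",
    "VolumeFormatError",
]

OUT_OF_BOUNDS = (-1, -1, -1)
"""Sentinel returned by :func:`world_to_cell` for points outside the grid."""


class GridError(ValueError):
    """Invalid grid geometry or mismatched grids."""


class VolumeFormatError(IOError):
    """Malformed or unsupported volume file."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular axis-aligned 3D grid.

    Parameters
    ----------
    origin : (3,) array-like
        World coordinate (mm) of the corner of voxel (0, 0, 0).
    spacing : (3,) array-like
        Positive voxel edge lengths (mm).
    shape : (3,) tuple of int
        Voxel counts per axis, each >= 1.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        origin = tuple(float(v) for v in np.asarray(self.origin, dtype=float))
        spacing = tuple(float(v) for v in np.asarray(self.spacing, dtype=float))
        shape = tuple(int(v) for v in self.shape)
        if len(origin) != 3 or len(spacing) != 3 or len(shape) != 3:
            raise GridError("origin, spacing and shape must each have 3 entries")
        if any(s <= 0 for s in spacing):
            raise GridError(f"spacings must be positive, got {spacing}")
        if any(n < 1 for n in shape):
            raise GridError(f"shape must be >= 1 per axis, got {shape}")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "shape", shape)

    # -- coordinate transforms -------------------------------------------------

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (float) index coordinates of world points."""
        points = np.asarray(points, dtype=float)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates of continuous index coordinates (corner origin)."""
        indices = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + indices * np.asarray(self.spacing)

    def cell_centers_axis(self, axis: int) -> np.ndarray:
        o, s, n = self.origin[axis], self.spacing[axis], self.shape[axis]
        return o + (np.arange(n) + 0.5) * s

    def cell_center(self, index: tuple[int, int, int]) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(index) + 0.5) * np.asarray(self.spacing)

    @property
    def extent(self) -> np.ndarray:
        """(2, 3) array of world [min, max] corners."""
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.shape) * np.asarray(self.spacing)
        return np.stack([lo, hi])

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the half-open grid box."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo, hi = self.extent
        return np.all((pts >= lo) & (pts < hi), axis=-1)

    # -- NIfTI affine (voxel-center convention) --------------------------------

    def to_affine(self) -> np.ndarray:
        """4x4 affine mapping integer voxel index -> world voxel center."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = np.asarray(self.origin) + 0.5 * np.asarray(self.spacing)
        return aff

    @classmethod
    def from_affine(cls, affine: np.ndarray, shape: tuple[int, int, int]) -> "VoxelGrid":
        affine = np.asarray(affine, dtype=float)
        rot = affine[:3, :3]
        if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
            raise VolumeFormatError("only axis-aligned (diagonal) affines are supported")
        spacing = np.diag(rot)
        if np.any(spacing <= 0):
            raise VolumeFormatError("affine must have positive diagonal scales")
        origin = affine[:3, 3] - 0.5 * spacing
        return cls(tuple(origin), tuple(spacing), tuple(int(s) for s in shape[:3]))


def world_to_cell(point: np.ndarray, grid: VoxelGrid) -> tuple[int, int, int]:
    """Map a world point to its half-open cell index, or an out-of-bounds marker.

    The cell for index ``i`` covers ``origin + i*spacing <= x < origin +
    (i+1)*spacing`` on each axis.  Points outside the grid return
    :data:`OUT_OF_BOUNDS` rather than raising.
    """
    idx = np.floor(grid.world_to_index(point)).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid.shape)):
        return OUT_OF_BOUNDS
    return tuple(int(i) for i in idx)


def world_to_cells(points: np.ndarray, grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`world_to_cell`.

    Returns ``(indices, in_bounds)`` where ``indices`` is (n, 3) int (undefined
    rows where ``in_bounds`` is False).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = np.floor(grid.world_to_index(pts)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=-1)
    return idx, ok


@dataclass
class ScalarVolume:
    """Scalar field on a :class:`VoxelGrid` (e.g. voltage in V, density counts)."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def sample_trilinear(self, points: np.ndarray, outside: float = 0.0) -> np.ndarray:
        """Trilinear interpolation at world points, using voxel-center nodes.

        Points outside the center lattice's convex hull are clamped to the edge
        value if still inside the grid box, and return ``outside`` beyond it.
        """
        from scipy.interpolate import RegularGridInterpolator

        axes = [self.grid.cell_centers_axis(a) for a in range(3)]
        interp = RegularGridInterpolator(
            axes, np.asarray(self.values, dtype=float),
            bounds_error=False, fill_value=None,  # linear extrapolation at edges
        )
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = interp(pts)
        inside = self.grid.contains(pts)
        out = np.where(inside, out, outside)
        return out if np.asarray(points).ndim > 1 else float(out[0])


@dataclass
class TensorVolume:
    """Symmetric 3x3 tensor field, stored as an (nx, ny, nz, 3, 3) array."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape + (3, 3):
            raise GridError(
                f"tensor values shape {self.values.shape} != {self.grid.shape + (3, 3)}"
            )

    def validate(self, eig_tol: float = 1e-9) -> None:
        """Check symmetry and positive semi-definiteness."""
        v = self.values
        if not np.allclose(v, np.swapaxes(v, -1, -2), atol=1e-9):
            raise GridError("tensor volume is not symmetric")
        eigvals = np.linalg.eigvalsh(v.reshape(-1, 3, 3))
        if eigvals.min() < -eig_tol:
            raise GridError(f"tensor volume has negative eigenvalue {eigvals.min():g}")


@dataclass
class LabelVolume:
    """Non-negative integer label field with a label -> region-name table.

    Label 0 is reserved for background and never appears in ``names``.
    """

    grid: VoxelGrid
    values: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise GridError("label values must be integers")
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"label shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.values.min() < 0:
            raise GridError("labels must be non-negative")
        if 0 in self.names:
            raise GridError("label 0 is reserved for background")

    def present_labels(self) -> np.ndarray:
        labels = np.unique(self.values)
        return labels[labels != 0]

    def check_table(self) -> None:
        missing = set(self.present_labels().tolist()) - set(self.names)
        if missing:
            raise GridError(f"labels without a region name: {sorted(missing)}")


# -- NIfTI I/O ------------------------------------------------------------------


def write_volume(path, volume) -> None:
    """Write a Scalar/Tensor/Label volume as NIfTI (.nii or .nii.gz).

    Tensor volumes are stored as 5D (x, y, z, 3, 3) images; label name tables
    are *not* embedded (see :mod:`stimdense.regions` for the sidecar table).
    """
    affine = volume.grid.to_affine()
    data = np.asarray(volume.values)
    if isinstance(volume, LabelVolume):
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.grid.spacing + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def read_volume(path, kind: str = "scalar"):
    """Read a NIfTI volume as ``kind`` in {'scalar', 'tensor', 'label'}."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read volume {path}: {exc}") from exc
    data = np.asarray(img.dataobj)
    grid = VoxelGrid.from_affine(img.affine, data.shape[:3])
    if kind == "scalar":
        if data.ndim != 3:
            raise VolumeFormatError(f"expected 3D scalar volume, got shape {data.shape}")
        return ScalarVolume(grid, data.astype(float))
    if kind == "tensor":
        if data.ndim != 5 or data.shape[3:] != (3, 3):
            raise VolumeFormatError(f"expected (x,y,z,3,3) tensor volume, got {data.shape}")
        return TensorVolume(grid, data)
    if kind == "label":
        if data.ndim != 3:
            raise VolumeFormatError(f"expected 3D label volume, got shape {data.shape}")
        return LabelVolume(grid, np.rint(data).astype(np.int32))
    raise ValueError(f"unknown volume kind {kind!r}")
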