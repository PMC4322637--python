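"""Streamline containers, arc-length resampling, and TRK/TCK I/O.

Streamlines are ordered 3D polylines in world millimetres.  Resampling at a
fixed arc-length step underlies node-of-Ranvier placement (0.5 mm internodal
spacing), so it is exact-by-construction: returned points lie *on* the
original polyline at arc-length multiples of the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Streamline",
    "StreamlineSet",
    "resample_streamline",
    "read_streamlines",
    "write_streamlines",
    "FiberTooShortError",
    "StreamlineFormatError",
]


class FiberTooShortError(ValueError):
    """Polyline arc length shorter than the requested resampling step."""


class StreamlineFormatError(IOError):
    """Malformed or unsupported streamline file."""


@dataclass
class Streamline:
    """One tracked trajectory: ordered world-mm points with seed provenance."""

    points: np.ndarray
    seed_index: int = -1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError("a streamline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("consecutive streamline points must be distinct")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class StreamlineSet:
    """Ordered collection of streamlines; order is preserved through I/O."""

    streamlines: list[Streamline] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i):
        return self.streamlines[i]

    def append(self, s: Streamline) -> None:
        self.streamlines.append(s)


def resample_streamline(s: Streamline, step: float) -> Streamline:
    """Resample a polyline at fixed arc-length intervals starting at its first point.

    Returned points lie on the original polyline at arc lengths
    ``0, step, 2*step, ...`` up to the total length (phase 0: the first input
    point is always the first output point).  Consecutive output points are
    ``step`` apart in arc length along the input, though their chord distance
    can be slightly shorter on curved paths.

    Raises
    ------
    FiberTooShortError
        If the polyline's total arc length is below ``step``.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    pts = s.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total < step:
        raise FiberTooShortError(
            f"arc length {total:.4f} mm < step {step} mm"
        )
    n_out = int(np.floor(total / step + 1e-9)) + 1
    targets = np.arange(n_out) * step
    # interpolate each coordinate against arc length
    out = np.column_stack([np.interp(targets, cum, pts[:, k]) for k in range(3)])
    return Streamline(out, seed_index=s.seed_index)


# -- TRK / TCK I/O ---------------------------------------------------------------


def write_streamlines(path, sset: StreamlineSet, grid=None) -> None:
    """Write a StreamlineSet to .trk or .tck (by extension), coordinates in world mm.

    ``grid`` (a :class:`~stimdense.grids.VoxelGrid`) optionally provides TRK
    header geometry; TCK does not need it.
    """
    path = Path(path)
    arrays = [s.points.astype(np.float32) for s in sset]
    tractogram = nib.streamlines.Tractogram(arrays, affine_to_rasmm=np.eye(4))
    if path.suffix == ".trk":
        header = {}
        if grid is not None:
            header["voxel_to_rasmm"] = grid.to_affine().astype(np.float32)
            header["dimensions"] = np.asarray(grid.shape, dtype=np.int16)
            header["voxel_sizes"] = np.asarray(grid.spacing, dtype=np.float32)
        f = nib.streamlines.TrkFile(tractogram, header=header)
    elif path.suffix == ".tck":
        f = nib.streamlines.TckFile(tractogram)
    else:
        raise StreamlineFormatError(f"unsupported streamline format {path.suffix!r}")
    f.save(str(path))


def read_streamlines(path) -> StreamlineSet:
    """Read .trk/.tck streamlines back into world mm."""
    path = Path(path)
    if path.suffix not in (".trk", ".tck"):
        raise StreamlineFormatError(f"unsupported streamline format {path.suffix!r}")
    try:
        f = nib.streamlines.load(str(path))
    except Exception as exc:
        raise StreamlineFormatError(f"cannot read {path}: {exc}") from exc
    out = StreamlineSet()
    for arr in f.tractogram.streamlines:
        out.append(Streamline(np.asarray(arr, dtype=float)))
    return out
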