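"""Activation density heat maps and Hadamard contrast maps.

The density map voxelizes active-fiber geometry on a 1 mm^3 Cartesian grid:
each cell's value is the number of *distinct* active fibers with at least one
node of Ranvier inside the cell (a fiber with several nodes in one cell still
counts once there, and contributes to every distinct cell holding any of its
nodes).  The counting unit is the node, not the path: a fiber whose path
clips a cell corner without a node inside contributes nothing to that cell.

Contrast maps isolate pathways characteristic of one electrode-placement pair
versus another: the elementwise (Hadamard) product of the pair's maps
highlights cells dense in both, and the difference of the two pair products
is signed — positive where the first pair dominates, negative for the second.

Intensity thresholding is provided for display only and never feeds the
quantitative operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridError, ScalarVolume, VoxelGrid, world_to_cells

__all__ = [
    "DensityHeatMap",
    "ContrastMap",
    "grid_for_fibers",
    "compute_density",
    "to_image",
    "threshold_map",
    "hadamard_contrast",
]


@dataclass
class DensityHeatMap:
    """Per-cell distinct-active-fiber counts on a voxel grid."""

    grid: VoxelGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("density counts must be integers")
        if self.counts.shape != self.grid.shape:
            raise GridError(f"counts shape {self.counts.shape} != grid {self.grid.shape}")
        if self.counts.min(initial=0) < 0:
            raise ValueError("density counts must be non-negative")


@dataclass
class ContrastMap:
    """Signed per-cell contrast between two pairs of density maps."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise GridError(f"values shape {self.values.shape} != grid {self.grid.shape}")


def grid_for_fibers(
    node_position_lists: list[np.ndarray],
    spacing: float = 1.0,
    pad_mm: float = 2.0,
) -> VoxelGrid:
    """Integer-mm grid covering all fiber nodes with padding.

    The origin is snapped down to whole millimetres so maps from different
    runs over the same anatomy align cell-for-cell.
    """
    if not node_position_lists:
        raise ValueError("need at least one fiber to define a grid extent")
    allpts = np.vstack(node_position_lists)
    lo = np.floor(allpts.min(axis=0) - pad_mm)
    hi = np.ceil(allpts.max(axis=0) + pad_mm)
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    return VoxelGrid(tuple(lo), (spacing,) * 3, tuple(int(n) for n in shape))


def compute_density(
    active_axons: list[np.ndarray], grid: VoxelGrid
) -> DensityHeatMap:
    """Count distinct active fibers with >= 1 node of Ranvier per grid cell."""
    counts = np.zeros(grid.shape, dtype=np.int64)
    for nodes in active_axons:
        idx, ok = world_to_cells(np.asarray(nodes, dtype=float), grid)
        if not ok.any():
            continue
        cells = np.unique(idx[ok], axis=0)  # dedup: one fiber counts once per cell
        counts[cells[:, 0], cells[:, 1], cells[:, 2]] += 1
    return DensityHeatMap(grid, counts)


def to_image(h: DensityHeatMap) -> ScalarVolume:
    """Lossless conversion of a density map to a scalar 3D image."""
    return ScalarVolume(h.grid, h.counts.astype(float))


def threshold_map(h: DensityHeatMap, percentile: float) -> DensityHeatMap:
    """Zero cells below the given percentile of the nonzero-count distribution.

    Display aid only — quantitative operations must consume the unthresholded
    map.  Percentile 0 is the identity; percentile 100 keeps only maximal
    cells.
    """
    if not (0.0 <= percentile <= 100.0):
        raise ValueError(f"percentile must be in [0, 100], got {percentile}")
    counts = np.asarray(h.counts)
    nonzero = counts[counts > 0]
    if nonzero.size == 0:
        return DensityHeatMap(h.grid, counts.copy())
    cut = np.percentile(nonzero, percentile)
    out = np.where(counts >= cut, counts, 0)
    return DensityHeatMap(h.grid, out)


def hadamard_contrast(
    a: DensityHeatMap,
    b: DensityHeatMap,
    c: DensityHeatMap,
    d: DensityHeatMap,
    normalize: bool = False,
) -> ContrastMap:
    """Signed pairwise contrast (a .* b) - (c .* d) on a shared grid.

    Positive cells mark predominance of the (a, b) placement pair, negative
    cells the (c, d) pair; swapping the pairs negates the map exactly.  With
    ``normalize`` each map is divided by its maximum count first, which
    removes the bias from unequal total fiber counts between models.
    """
    grids = [m.grid for m in (a, b, c, d)]
    if any(g != grids[0] for g in grids[1:]):
        raise GridError("all four density maps must share the same grid")
    if normalize:
        arrs = []
        for m in (a, b, c, d):
            peak = m.counts.max()
            arrs.append(m.counts / peak if peak > 0 else m.counts.astype(float))
        va, vb, vc, vd = arrs
        values = va * vb - vc * vd
    else:
        va, vb, vc, vd = (m.counts.astype(np.int64) for m in (a, b, c, d))
        values = va * vb - vc * vd
    return ContrastMap(grids[0], values)
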