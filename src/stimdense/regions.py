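"""Per-region quantification of active-fiber cortical projections.

A label atlas (non-negative integer labels, 0 = background, with a region
name table) is resampled onto the heat-map grid by nearest neighbor — labels
are categorical, so value interpolation is meaningless.  A fiber "reaches" a
region when at least one of its nodes of Ranvier lies in a cell carrying that
region's label; it then counts exactly once for that region no matter how
many of the region's cells it crosses (this mirrors the heat map's counting
unit and avoids over-representing fibers that course through many voxels of
one region).  Fibers reaching no region are excluded from percentages under
the default denominator policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridError, LabelVolume, VoxelGrid, world_to_cells

__all__ = [
    "RegionAtlas",
    "RegionReport",
    "resample_labels",
    "count_region_fibers",
    "region_percentages",
    "compare_models",
    "read_region_table",
    "write_region_table",
]


@dataclass
class RegionAtlas:
    """Label volume plus region-id -> name table."""

    labels: LabelVolume

    def __post_init__(self) -> None:
        self.labels.check_table()

    @property
    def names(self) -> dict[int, str]:
        return self.labels.names

    @property
    def grid(self) -> VoxelGrid:
        return self.labels.grid


def read_region_table(path) -> dict[int, str]:
    """Read a two-column (label, name) TSV region table."""
    df = pd.read_csv(path, sep="\t", dtype={"label": int, "name": str})
    return dict(zip(df["label"], df["name"]))


def write_region_table(path, names: dict[int, str]) -> None:
    pd.DataFrame(
        {"label": list(names), "name": [names[k] for k in names]}
    ).to_csv(path, sep="\t", index=False)


def resample_labels(atlas: RegionAtlas, grid: VoxelGrid) -> LabelVolume:
    """Nearest-neighbor resampling of the atlas onto a target grid.

    Each target cell inherits the label of the atlas voxel containing its
    center; no new labels can appear.  Cells whose centers fall outside the
    atlas become background.
    """
    lo_a, hi_a = atlas.grid.extent
    lo_g, hi_g = grid.extent
    if np.any(hi_a <= lo_g) or np.any(hi_g <= lo_a):
        raise GridError("atlas and target grid extents do not overlap")
    centers = np.stack(
        np.meshgrid(*[grid.cell_centers_axis(a) for a in range(3)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    idx, ok = world_to_cells(centers, atlas.grid)
    out = np.zeros(len(centers), dtype=atlas.labels.values.dtype)
    out[ok] = atlas.labels.values[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return LabelVolume(grid, out.reshape(grid.shape), dict(atlas.names))


def count_region_fibers(
    active_axons: list[np.ndarray], cell_labels: LabelVolume
) -> tuple[dict[int, int], list[set[int]]]:
    """Unique active-fiber count per region, plus each fiber's reached-region set.

    A fiber increments region R by exactly 1 iff >= 1 of its nodes lies in an
    R-labeled cell; one fiber may count toward several distinct regions.
    """
    counts: dict[int, int] = {label: 0 for label in cell_labels.names}
    reached: list[set[int]] = []
    for nodes in active_axons:
        idx, ok = world_to_cells(np.asarray(nodes, dtype=float), cell_labels.grid)
        labels = (
            np.unique(cell_labels.values[idx[ok, 0], idx[ok, 1], idx[ok, 2]])
            if ok.any()
            else np.array([], dtype=int)
        )
        regions = {int(l) for l in labels if l != 0}
        reached.append(regions)
        for r in regions:
            counts[r] = counts.get(r, 0) + 1
    return counts, reached


@dataclass
class RegionReport:
    """Per-region unique active-fiber counts and percentages."""

    counts: dict[int, int]
    percentages: dict[int, float]
    names: dict[int, str]
    denominator: int
    denominator_policy: str
    n_active: int
    n_excluded: int    # active fibers reaching no region

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": r,
                "region": self.names.get(r, str(r)),
                "count": self.counts.get(r, 0),
                "percent": self.percentages.get(r, 0.0),
            }
            for r in sorted(self.counts)
        ]
        return pd.DataFrame(rows)


def region_percentages(
    counts: dict[int, int],
    reached: list[set[int]],
    names: dict[int, str],
    policy: str = "region_reaching",
) -> RegionReport:
    """Percentages of active fibers per region under a declared denominator.

    ``region_reaching`` (default): denominator = active fibers reaching at
    least one region, i.e. fibers that reach no cortical region are excluded.
    ``all_active``: denominator = all classified-active fibers.
    """
    n_active = len(reached)
    n_reaching = sum(1 for s in reached if s)
    n_excluded = n_active - n_reaching
    if policy == "region_reaching":
        denom = n_reaching
    elif policy == "all_active":
        denom = n_active
    else:
        raise ValueError(f"unknown percentage policy {policy!r}")
    if denom == 0:
        import warnings

        warnings.warn("no active fibers in the denominator; empty region report")
        percentages = {r: 0.0 for r in counts}
    else:
        percentages = {r: 100.0 * c / denom for r, c in counts.items()}
    return RegionReport(
        counts=dict(counts),
        percentages=percentages,
        names=dict(names),
        denominator=denom,
        denominator_policy=policy,
        n_active=n_active,
        n_excluded=n_excluded,
    )


def compare_models(
    reports: list[RegionReport],
    top_k: int = 5,
    model_names: list[str] | None = None,
) -> pd.DataFrame:
    """Side-by-side ranking of each model's top-k regions by percentage.

    Ties are broken by region id (ascending).  Rows are ranks 1..top_k;
    columns give each model's region name and percentage.
    """
    if model_names is None:
        model_names = [f"model_{i + 1}" for i in range(len(reports))]
    if len(model_names) != len(reports):
        raise ValueError("model_names must match reports")
    table: dict[str, list] = {"rank": []}
    ranked_all = []
    for rep in reports:
        ranked = sorted(
            rep.counts, key=lambda r: (-rep.percentages.get(r, 0.0), r)
        )[:top_k]
        ranked_all.append(ranked)
    n_rows = max((len(r) for r in ranked_all), default=0)
    table["rank"] = list(range(1, n_rows + 1))
    for name, rep, ranked in zip(model_names, reports, ranked_all):
        regions, pcts = [], []
        for i in range(n_rows):
            if i < len(ranked):
                r = ranked[i]
                regions.append(rep.names.get(r, str(r)))
                pcts.append(rep.percentages.get(r, 0.0))
            else:
                regions.append("")
                pcts.append(np.nan)
        table[f"{name}_region"] = regions
        table[f"{name}_percent"] = pcts
    return pd.DataFrame(table)
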