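"""Synthetic phantoms with known ground truth for every pipeline stage.

A phantom is a small (default 60 mm cube) digital specimen holding straight
or arc-shaped fiber bundles embedded in isotropic background tissue: each
bundle is a tube whose voxels carry the local bundle tangent as a fiber
orientation and a prolate diffusion tensor aligned with it.  Optional CSF
slabs terminate tracking, and axis-aligned region slabs play the role of the
cortical label atlas.  Because bundle membership is analytic, every
downstream count (tracking recovery, activation, density, region reach) can
be checked against construction ground truth.

The two-placement scenario mirrors a comparative electrode study: one
electrode pose abuts bundle A and a second pose, shifted 4 mm, abuts bundle
B, giving contrast maps and region rankings a fixture with a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .field import ElectrodeModel
from .grids import LabelVolume, TensorVolume, VoxelGrid
from .regions import RegionAtlas
from .tracking import OrientationField

__all__ = [
    "BundleSpec",
    "RegionSlab",
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "make_two_placement_scenario",
]

# prolate tensor eigenvalues inside bundles, mm^2/s (white-matter-like)
LAMBDA_PARALLEL = 1.7e-3
LAMBDA_PERP = 0.3e-3
# isotropic background / CSF diffusivities, mm^2/s
D_BACKGROUND = 0.7e-3
D_CSF = 3.0e-3


@dataclass(frozen=True)
class BundleSpec:
    """One fiber bundle: a straight or circular-arc tube.

    straight: ``point`` + ``direction`` define the centerline.
    arc: circle of ``arc_radius`` about ``arc_center`` in the plane normal to
    ``arc_normal``; ``arc_start_deg``/``arc_end_deg`` bound the used portion.
    """

    name: str
    kind: str = "straight"          # 'straight' | 'arc'
    point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    arc_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    arc_normal: tuple[float, float, float] = (0.0, 0.0, 1.0)
    arc_radius: float = 20.0
    arc_start_deg: float = 0.0
    arc_end_deg: float = 180.0
    tube_radius: float = 3.0
    dispersion_deg: float = 0.0

    def centerline_distance_and_tangent(
        self, pts: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Distance of points to the centerline and the local unit tangent."""
        pts = np.atleast_2d(pts)
        if self.kind == "straight":
            d = np.asarray(self.direction, dtype=float)
            d = d / np.linalg.norm(d)
            rel = pts - np.asarray(self.point)
            axial = rel @ d
            radial = rel - axial[:, None] * d
            dist = np.linalg.norm(radial, axis=1)
            tangent = np.broadcast_to(d, pts.shape).copy()
            return dist, tangent
        if self.kind == "arc":
            n = np.asarray(self.arc_normal, dtype=float)
            n = n / np.linalg.norm(n)
            rel = pts - np.asarray(self.arc_center)
            in_plane = rel - (rel @ n)[:, None] * n
            rho = np.linalg.norm(in_plane, axis=1)
            # closest point on the full circle; angular bounds gate membership
            with np.errstate(invalid="ignore", divide="ignore"):
                radial_dir = np.where(rho[:, None] > 1e-12, in_plane / rho[:, None], 0.0)
            closest = np.asarray(self.arc_center) + self.arc_radius * radial_dir
            dist = np.linalg.norm(pts - closest, axis=1)
            u, v = _plane_basis(n)
            ang = np.degrees(np.arctan2(in_plane @ v, in_plane @ u)) % 360.0
            if self.arc_end_deg - self.arc_start_deg >= 360.0:
                in_span = np.ones(len(pts), dtype=bool)  # full circle
            else:
                lo = self.arc_start_deg % 360.0
                hi = self.arc_end_deg % 360.0
                in_span = (
                    (ang >= lo) & (ang <= hi) if lo <= hi else (ang >= lo) | (ang <= hi)
                )
            dist = np.where(in_span & (rho > 1e-12), dist, np.inf)
            tangent = np.cross(n, radial_dir)
            norms = np.linalg.norm(tangent, axis=1, keepdims=True)
            tangent = np.where(norms > 1e-12, tangent / norms, 0.0)
            return dist, tangent
        raise ValueError(f"unknown bundle kind {self.kind!r}")


def _plane_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


@dataclass(frozen=True)
class RegionSlab:
    """Axis-aligned labeled box standing in for a cortical region."""

    name: str
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]


@dataclass
class PhantomSpec:
    """Geometry and sampling of a synthetic specimen."""

    extent_mm: float = 60.0
    orientation_spacing: float = 2.0
    label_spacing: float = 1.0
    bundles: list[BundleSpec] = dc_field(default_factory=list)
    csf_slabs: list[tuple[tuple[float, float, float], tuple[float, float, float]]] = (
        dc_field(default_factory=list)
    )
    regions: list[RegionSlab] = dc_field(default_factory=list)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.extent_mm <= 0 or self.orientation_spacing <= 0 or self.label_spacing <= 0:
            raise ValueError("extent and spacings must be positive")
        if len(self.bundles) == 0:
            raise ValueError("phantom needs at least one bundle")
        for b in self.bundles:
            if b.tube_radius <= 0:
                raise ValueError(f"bundle {b.name!r} tube radius must be positive")


@dataclass
class Phantom:
    """Generated phantom volumes plus analytic ground truth."""

    spec: PhantomSpec
    orientation: OrientationField
    tensors: TensorVolume
    csf_mask: LabelVolume
    atlas: RegionAtlas
    region_ids: dict[str, int]

    def bundle_membership(self, points: np.ndarray) -> np.ndarray:
        """Index of the bundle whose tube contains each point (-1 outside all)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(len(pts), -1, dtype=int)
        for k, b in enumerate(self.spec.bundles):
            dist, _ = b.centerline_distance_and_tangent(pts)
            out[(out == -1) & (dist <= b.tube_radius)] = k
        return out


def _make_grid(extent: float, spacing: float) -> VoxelGrid:
    n = int(round(extent / spacing))
    return VoxelGrid((0.0, 0.0, 0.0), (spacing,) * 3, (n, n, n))


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build orientation field, tensors, CSF mask and atlas from a spec.

    Deterministic for a given spec (the rng_seed matters only to downstream
    stochastic consumers such as the tracker).
    """
    spec.validate()
    ogrid = _make_grid(spec.extent_mm, spec.orientation_spacing)
    lgrid = _make_grid(spec.extent_mm, spec.label_spacing)

    centers = np.stack(
        np.meshgrid(*[ogrid.cell_centers_axis(a) for a in range(3)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    n_vox = len(centers)
    directions = np.zeros((n_vox, 2, 3))
    fractions = np.zeros((n_vox, 2))
    dispersion = np.zeros(n_vox)
    slot = np.zeros(n_vox, dtype=int)

    tensors = np.zeros((n_vox, 3, 3))
    tensors[:] = D_BACKGROUND * np.eye(3)

    for b in spec.bundles:
        dist, tangent = b.centerline_distance_and_tangent(centers)
        inside = dist <= b.tube_radius
        take = inside & (slot < 2)
        s = slot[take]
        directions[np.flatnonzero(take), s] = tangent[take]
        fractions[np.flatnonzero(take), s] = 1.0
        dispersion[take] = np.maximum(dispersion[take], b.dispersion_deg)
        slot[take] += 1
        # prolate tensor aligned with the tangent (first bundle wins overlaps)
        first = inside & (slot == 1)
        t = tangent[first]
        outer = t[:, :, None] * t[:, None, :]
        tensors[first] = LAMBDA_PERP * np.eye(3) + (LAMBDA_PARALLEL - LAMBDA_PERP) * outer

    multi = slot == 2
    fractions[multi] = 0.5  # two crossing populations share the voxel

    csf_o = np.zeros(n_vox, dtype=bool)
    lcenters = np.stack(
        np.meshgrid(*[lgrid.cell_centers_axis(a) for a in range(3)], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    csf_l = np.zeros(len(lcenters), dtype=bool)
    for lo, hi in spec.csf_slabs:
        lo_a, hi_a = np.asarray(lo), np.asarray(hi)
        csf_o |= np.all((centers >= lo_a) & (centers < hi_a), axis=1)
        csf_l |= np.all((lcenters >= lo_a) & (lcenters < hi_a), axis=1)
    tensors[csf_o] = D_CSF * np.eye(3)
    fractions[csf_o] = 0.0

    labels = np.zeros(len(lcenters), dtype=np.int32)
    region_ids: dict[str, int] = {}
    for i, slab in enumerate(spec.regions, start=1):
        region_ids[slab.name] = i
        lo_a, hi_a = np.asarray(slab.lo), np.asarray(slab.hi)
        inside = np.all((lcenters >= lo_a) & (lcenters < hi_a), axis=1)
        labels[inside] = i

    orientation = OrientationField(
        grid=ogrid,
        directions=directions.reshape(ogrid.shape + (2, 3)),
        fractions=fractions.reshape(ogrid.shape + (2,)),
        dispersion_deg=dispersion.reshape(ogrid.shape),
    )
    tensor_volume = TensorVolume(ogrid, tensors.reshape(ogrid.shape + (3, 3)))
    csf_mask = LabelVolume(
        ogrid, csf_o.reshape(ogrid.shape).astype(np.int32), {1: "csf"}
    )
    atlas = RegionAtlas(
        LabelVolume(
            lgrid,
            labels.reshape(lgrid.shape),
            {i: name for name, i in region_ids.items()},
        )
    )
    return Phantom(
        spec=spec,
        orientation=orientation,
        tensors=tensor_volume,
        csf_mask=csf_mask,
        atlas=atlas,
        region_ids=region_ids,
    )


@dataclass
class TwoPlacementScenario:
    """Shared phantom plus two electrode poses 4 mm apart with ground truth."""

    phantom: Phantom
    electrodes: tuple[ElectrodeModel, ElectrodeModel]
    abutting_bundles: tuple[str, str]     # bundle name nearest each placement
    expected_top_regions: tuple[str, str]  # region each placement's bundle enters


def make_two_placement_scenario(
    spec: PhantomSpec | None = None,
    shift_mm: float = 4.0,
) -> TwoPlacementScenario:
    """Comparative-placement fixture: two poses abutting two disjoint bundles.

    With the default spec, bundle A runs along z at x = 26 and bundle B at
    x = 26 + 2 * shift + 4; the first electrode sits between them, 4 mm from
    bundle A's centerline, and the second is the first shifted ``shift_mm``
    laterally towards bundle B.
    """
    if spec is None:
        xa, e1x = 26.0, 30.0
        e2x = e1x + shift_mm
        xb = e2x + 4.0
        spec = PhantomSpec(
            bundles=[
                BundleSpec(name="bundle_a", kind="straight",
                           point=(xa, 30.0, 0.0), direction=(0.0, 0.0, 1.0),
                           tube_radius=3.0),
                BundleSpec(name="bundle_b", kind="straight",
                           point=(xb, 30.0, 0.0), direction=(0.0, 0.0, 1.0),
                           tube_radius=3.0),
            ],
            csf_slabs=[((0.0, 0.0, 0.0), (60.0, 60.0, 2.0))],
            regions=[
                RegionSlab("region_a", (xa - 8.0, 22.0, 50.0), (xa + 6.0, 38.0, 58.0)),
                RegionSlab("region_b", (xb - 6.0, 22.0, 50.0), (xb + 8.0, 38.0, 58.0)),
            ],
        )
        abutting = ("bundle_a", "bundle_b")
        expected = ("region_a", "region_b")
        base = (e1x, 30.0, 27.75)  # contact-0 midpoint lands at z = 30
    else:
        spec.validate()
        if len(spec.bundles) < 2 or len(spec.regions) < 2:
            raise ValueError("a custom two-placement spec needs >= 2 bundles and regions")
        abutting = (spec.bundles[0].name, spec.bundles[1].name)
        expected = (spec.regions[0].name, spec.regions[1].name)
        c = spec.extent_mm / 2.0
        base = (c - shift_mm / 2.0, c, c - 2.25)
    phantom = make_phantom(spec)
    e1 = ElectrodeModel(tip_position=base, axis=(0.0, 0.0, 1.0), active_contact=0)
    e2 = ElectrodeModel(
        tip_position=(base[0] + shift_mm, base[1], base[2]),
        axis=(0.0, 0.0, 1.0),
        active_contact=0,
    )
    lo, hi = phantom.orientation.grid.extent
    for e in (e1, e2):
        if np.any(np.asarray(e.tip_position) < lo) or np.any(np.asarray(e.tip_position) >= hi):
            raise ValueError("electrode pose outside the phantom extent")
    return TwoPlacementScenario(
        phantom=phantom,
        electrodes=(e1, e2),
        abutting_bundles=abutting,
        expected_top_regions=expected,
    )
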