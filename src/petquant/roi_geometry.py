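"""ROI/VOI placement for contrast-phantom analysis.

Implements the standard single-slice circular ROI (diameter equal to
the physical inner sphere diameter, placed on the transaxial plane
where the sphere is most visible), the matching spherical VOI, and the
background grid of 12 circular ROIs per sphere size replicated on the
central plane and at axial offsets of +/-1 cm and +/-2 cm (60
background ROIs per sphere size in total).

Voxel membership is binary center-inclusion: a voxel belongs to an ROI
iff its center lies inside the circle/sphere. Background ROI centers
are shared (concentric) across sphere sizes and are laid out uniformly
on a configurable circle, checked against a configurable clearance
margin from every sphere surface and against cylinder containment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import GeometryError, InvalidSpecError
from .phantom_sim import GridSpec, Image3D, PhantomSpec, SphereSpec

__all__ = [
    "CircularROI",
    "SphericalVOI",
    "Mask",
    "ROISet",
    "rasterize_circular_roi",
    "rasterize_spherical_voi",
    "find_most_visible_slice",
    "build_background_grid",
    "build_roi_set",
    "BACKGROUND_AXIAL_OFFSETS_MM",
]

#: Axial plane offsets (mm) of the background ROI grid: the central
#: plane plus +/-1 cm and +/-2 cm.
BACKGROUND_AXIAL_OFFSETS_MM = (0.0, 10.0, -10.0, 20.0, -20.0)

#: Number of background ROIs per plane.
N_BACKGROUND_PER_PLANE = 12


@dataclass(frozen=True)
class CircularROI:
    """Single-slice circular ROI: in-plane center (mm), diameter (mm),
    0-based slice index."""

    center: tuple[float, float]
    diameter: float
    slice_index: int

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidSpecError("ROI diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class SphericalVOI:
    """Spherical VOI: world center (mm) and diameter (mm)."""

    center: tuple[float, float, float]
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidSpecError("VOI diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class Mask:
    """Boolean voxel membership on a grid."""

    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.shape:
            raise InvalidSpecError("mask shape does not match grid")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def values_in(self, img: Image3D) -> np.ndarray:
        return img.values[self.data]

    def mean_in(self, img: Image3D) -> float:
        return float(img.values[self.data].mean())


@dataclass
class ROISet:
    """Sphere ROIs/VOIs plus the per-sphere-size background grid.

    ``sphere_rois`` maps sphere inner diameter to (CircularROI,
    SphericalVOI); ``background_rois`` maps sphere inner diameter to the
    list of 60 background CircularROIs of that diameter. ``metadata``
    records layout parameters (plane slice mapping, layout radius,
    margin).
    """

    sphere_rois: dict[float, tuple[CircularROI, SphericalVOI]]
    background_rois: dict[float, list[CircularROI]]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """Plain-data serialization (centers, diameters, slice indices)."""
        return {
            "sphere_rois": {
                str(d): {
                    "slice_roi": {
                        "center_mm": list(roi.center),
                        "diameter_mm": roi.diameter,
                        "slice_index": roi.slice_index,
                    },
                    "voi": {
                        "center_mm": list(voi.center),
                        "diameter_mm": voi.diameter,
                    },
                }
                for d, (roi, voi) in self.sphere_rois.items()
            },
            "background_rois": {
                str(d): [
                    {
                        "center_mm": list(r.center),
                        "diameter_mm": r.diameter,
                        "slice_index": r.slice_index,
                    }
                    for r in rois
                ]
                for d, rois in self.background_rois.items()
            },
            "metadata": self.metadata,
        }


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def rasterize_circular_roi(roi: CircularROI, grid: GridSpec) -> Mask:
    """Binary mask of voxel centers inside the circle on one slice."""
    if not 0 <= roi.slice_index < grid.shape[2]:
        raise GeometryError(
            f"slice index {roi.slice_index} outside grid with "
            f"{grid.shape[2]} slices"
        )
    xs = grid.axis_coords(0) - roi.center[0]
    ys = grid.axis_coords(1) - roi.center[1]
    inside = xs[:, None] ** 2 + ys[None, :] ** 2 <= roi.radius**2
    data = np.zeros(grid.shape, dtype=bool)
    data[:, :, roi.slice_index] = inside
    mask = Mask(data, grid)
    if mask.voxel_count == 0:
        raise GeometryError(
            f"circular ROI at {roi.center} (d={roi.diameter} mm, slice "
            f"{roi.slice_index}) covers no voxel centers"
        )
    return mask


def rasterize_spherical_voi(voi: SphericalVOI, grid: GridSpec) -> Mask:
    """Binary mask of voxel centers inside the sphere."""
    xs = grid.axis_coords(0) - voi.center[0]
    ys = grid.axis_coords(1) - voi.center[1]
    zs = grid.axis_coords(2) - voi.center[2]
    inside = (
        xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
        <= voi.radius**2
    )
    mask = Mask(inside, grid)
    if mask.voxel_count == 0:
        raise GeometryError(
            f"spherical VOI at {voi.center} (d={voi.diameter} mm) covers "
            "no voxel centers"
        )
    return mask


# ---------------------------------------------------------------------------
# Sphere slice selection
# ---------------------------------------------------------------------------


def find_most_visible_slice(
    img: Image3D, sphere: SphereSpec, polarity: str = "hot"
) -> int:
    """Transaxial slice where the sphere is most visible.

    Searches within one sphere radius of the geometric center slice for
    the slice whose in-ROI mean (circular ROI of the sphere's inner
    diameter at the sphere's in-plane center) is maximal for hot
    spheres or minimal for cold spheres. Ties resolve to the slice
    nearest the geometric center, then to the lower index.
    """
    if polarity not in ("hot", "cold"):
        raise InvalidSpecError(f"polarity must be 'hot' or 'cold', got {polarity!r}")
    grid = img.grid
    zs = grid.axis_coords(2)
    cz = sphere.center[2]
    for axis, c in enumerate(sphere.center):
        coords = grid.axis_coords(axis)
        if not coords.min() - grid.voxel_size[axis] <= c <= coords.max() + grid.voxel_size[axis]:
            raise GeometryError(f"sphere center {sphere.center} outside image")
    center_idx = int(np.argmin(np.abs(zs - cz)))
    candidates = np.nonzero(np.abs(zs - cz) <= sphere.radius)[0]
    if candidates.size == 0:
        candidates = np.array([center_idx])
    xs = grid.axis_coords(0) - sphere.center[0]
    ys = grid.axis_coords(1) - sphere.center[1]
    inside = xs[:, None] ** 2 + ys[None, :] ** 2 <= sphere.radius**2
    if not inside.any():
        raise GeometryError(
            f"sphere at {sphere.center} covers no in-plane voxel centers"
        )
    scores = np.asarray(
        [float(img.values[:, :, int(idx)][inside].mean()) for idx in candidates]
    )
    key = -scores if polarity == "hot" else scores
    order = sorted(
        range(len(candidates)),
        key=lambda i: (key[i], abs(int(candidates[i]) - center_idx), int(candidates[i])),
    )
    return int(candidates[order[0]])


# ---------------------------------------------------------------------------
# Background grid
# ---------------------------------------------------------------------------


def _disc_to_point_distance(
    roi_center: tuple[float, float], roi_radius: float, z_plane: float,
    point: tuple[float, float, float],
) -> float:
    """Distance from a horizontal disc to a 3-D point."""
    d_ip = math.hypot(roi_center[0] - point[0], roi_center[1] - point[1])
    dz = z_plane - point[2]
    if d_ip <= roi_radius:
        return abs(dz)
    return math.hypot(d_ip - roi_radius, dz)


def build_background_grid(
    phantom: PhantomSpec,
    grid: GridSpec,
    central_slice: int | None = None,
    layout_radius: float = 90.0,
    margin: float = 15.0,
    angle_offset_deg: float = 15.0,
) -> ROISet:
    """Background ROI grid: 12 centers per plane on 5 planes per size.

    Twelve ROI centers are spaced uniformly on a circle of
    ``layout_radius`` (concentric across sphere sizes), rotated by
    ``angle_offset_deg`` to interleave with the spheres, on the central
    plane and at axial offsets of +/-1 cm and +/-2 cm (nearest-slice
    rounding). Every ROI must keep at least ``margin`` mm clearance
    from every sphere surface and lie entirely inside the cylinder;
    violations raise :class:`GeometryError` listing the offending ROIs.
    """
    diameters = sorted(s.inner_diameter for s in phantom.spheres)
    if not diameters:
        raise InvalidSpecError("phantom has no spheres")
    d_max = diameters[-1]

    zs = grid.axis_coords(2)
    if central_slice is None:
        z_spheres = float(np.mean([s.center[2] for s in phantom.spheres]))
        central_slice = int(np.argmin(np.abs(zs - z_spheres)))
    if not 0 <= central_slice < grid.shape[2]:
        raise GeometryError(f"central slice {central_slice} outside grid")
    z0 = zs[central_slice]

    violations: list[str] = []

    # 12 non-overlapping ROIs of the largest diameter must fit on the ring
    chord = 2.0 * layout_radius * math.sin(math.pi / N_BACKGROUND_PER_PLANE)
    if chord < d_max:
        violations.append(
            f"adjacent ROI spacing {chord:.1f} mm < largest diameter {d_max} mm"
        )
    if layout_radius + d_max / 2.0 > phantom.cylinder_radius:
        violations.append(
            f"largest ROIs (edge radius {layout_radius + d_max / 2.0:.1f} mm) "
            f"extend outside the cylinder (radius {phantom.cylinder_radius} mm)"
        )

    angles = np.deg2rad(angle_offset_deg) + 2.0 * np.pi * np.arange(
        N_BACKGROUND_PER_PLANE
    ) / N_BACKGROUND_PER_PLANE
    centers = [
        (layout_radius * math.cos(a), layout_radius * math.sin(a)) for a in angles
    ]

    plane_slices: list[int] = []
    for off in BACKGROUND_AXIAL_OFFSETS_MM:
        idx = int(np.argmin(np.abs(zs - (z0 + off))))
        plane_slices.append(idx)

    background: dict[float, list[CircularROI]] = {}
    for d in diameters:
        rois = []
        for off, idx in zip(BACKGROUND_AXIAL_OFFSETS_MM, plane_slices):
            z_plane = zs[idx]
            for c in centers:
                roi = CircularROI(c, d, idx)
                for s in phantom.spheres:
                    clearance = (
                        _disc_to_point_distance(c, d / 2.0, z_plane, s.center)
                        - s.radius
                    )
                    if clearance < margin:
                        violations.append(
                            f"background ROI d={d} mm at {c} (plane offset "
                            f"{off:+.0f} mm) is {clearance:.1f} mm from the "
                            f"{s.inner_diameter} mm sphere surface "
                            f"(margin {margin} mm)"
                        )
                rois.append(roi)
        background[d] = rois

    if violations:
        raise GeometryError(
            "infeasible background ROI layout:\n" + "\n".join(violations)
        )

    metadata = {
        "layout_radius_mm": layout_radius,
        "margin_mm": margin,
        "angle_offset_deg": angle_offset_deg,
        "central_slice": central_slice,
        "plane_slices": plane_slices,
        "axial_offsets_mm": list(BACKGROUND_AXIAL_OFFSETS_MM),
    }
    return ROISet(sphere_rois={}, background_rois=background, metadata=metadata)


def build_roi_set(
    img: Image3D,
    phantom: PhantomSpec,
    layout_radius: float = 90.0,
    margin: float = 15.0,
) -> ROISet:
    """Full ROI set for a phantom image: per-sphere single-slice ROI (on
    the most visible slice) and matching spherical VOI, plus the
    60-per-size background grid."""
    roi_set = build_background_grid(
        phantom, img.grid, layout_radius=layout_radius, margin=margin
    )
    for s in phantom.spheres:
        polarity = "hot" if s.concentration > phantom.background_concentration else "cold"
        idx = find_most_visible_slice(img, s, polarity)
        roi = CircularROI(s.center[:2], s.inner_diameter, idx)
        voi = SphericalVOI(s.center, s.inner_diameter)
        roi_set.sphere_rois[s.inner_diameter] = (roi, voi)
    return roi_set


def rasterize_background(
    roi_set: ROISet, grid: GridSpec
) -> dict[float, list[Mask]]:
    """Rasterize all background ROIs once (for reuse across images)."""
    return {
        d: [rasterize_circular_roi(r, grid) for r in rois]
        for d, rois in roi_set.background_rois.items()
    }
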