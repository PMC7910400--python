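"""Contrast-recovery and noise metrics for phantom images.

Implements the standard NEMA-style quantities for a hot/cold sphere
phantom:

* hot-sphere recovery coefficient
  ``RC_hot = ((C_sphere / C_bg) - 1) / ((A_hot / A_bg) - 1) * 100 %``,
* cold-sphere recovery coefficient
  ``RC_cold = (1 - C_sphere / C_bg) * 100 %``,
* percent background variability: sample SD of the K = 60
  background-ROI means over their mean, times 100,
* voxel noise (%): coefficient of variation of individual voxel values
  pooled over the background ROIs of one sphere size,

plus recovery-versus-noise trajectories across reconstruction
iterations, single-voxel-width line profiles normalized to the injected
activity, and the cps/kBq-to-percent sensitivity unit conversion.

RC values are not clamped: resolution-modelling reconstructions can
overshoot 100 % at sphere edges (Gibbs ringing), and that behaviour is
informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, InvalidSpecError, UndefinedContrastError
from .phantom_sim import GridSpec, Image3D, PhantomSpec
from .roi_geometry import Mask, ROISet

__all__ = [
    "SphereMeasurement",
    "TruthConcentrations",
    "LineProfile",
    "rc_hot",
    "rc_cold",
    "bg_variability",
    "voxel_noise",
    "measure_sphere",
    "analyze_phantom",
    "rc_noise_trajectory",
    "voxel_noise_replicates",
    "line_profile",
    "sensitivity_percent",
]


@dataclass(frozen=True)
class TruthConcentrations:
    """True (well-counter) activity concentrations in kBq/ml."""

    a_hot: float
    a_background: float

    def __post_init__(self) -> None:
        if self.a_background <= 0:
            raise InvalidSpecError("a_background must be > 0")
        if self.a_hot < 0:
            raise InvalidSpecError("a_hot must be >= 0")


@dataclass(frozen=True)
class SphereMeasurement:
    """ROI statistics feeding the recovery and variability formulas.

    ``c_sphere`` is the mean over the sphere ROI/VOI, ``c_background``
    the mean of the 60 background-ROI means, ``sd_background_means``
    their sample SD, and ``voxel_sd_background`` the sample SD of the
    pooled background voxel values.
    """

    c_sphere: float
    c_background: float
    sd_background_means: float
    voxel_sd_background: float
    mode: str = "single_slice"


@dataclass
class LineProfile:
    """Single-voxel-width profile normalized to injected activity.

    ``positions`` are mm along the segment (strictly increasing);
    ``values`` carry 1/ml-like units (kBq/ml divided by injected MBq).
    """

    positions: np.ndarray
    values: np.ndarray
    start: tuple[float, float, float]
    end: tuple[float, float, float]
    injected_activity_mbq: float


# ---------------------------------------------------------------------------
# Core formulas
# ---------------------------------------------------------------------------


def rc_hot(m: SphereMeasurement, truth: TruthConcentrations) -> float:
    """Hot-sphere recovery coefficient in percent (not clamped)."""
    if m.c_background <= 0:
        raise InvalidSpecError("c_background must be > 0 for recovery computation")
    true_ratio = truth.a_hot / truth.a_background
    if true_ratio == 1.0:
        raise UndefinedContrastError(
            "hot recovery undefined: true contrast ratio equals 1"
        )
    return ((m.c_sphere / m.c_background) - 1.0) / (true_ratio - 1.0) * 100.0


def rc_cold(m: SphereMeasurement) -> float:
    """Cold-sphere recovery coefficient in percent."""
    if m.c_background <= 0:
        raise InvalidSpecError("c_background must be > 0 for recovery computation")
    return (1.0 - m.c_sphere / m.c_background) * 100.0


def bg_variability(background_roi_means: Sequence[float]) -> float:
    """Percent background variability: sample SD over mean of the
    background-ROI means, times 100."""
    means = np.asarray(background_roi_means, dtype=float)
    if means.size < 2:
        raise InvalidSpecError("need at least 2 background ROI means")
    mean = means.mean()
    if mean == 0:
        raise InvalidSpecError("background mean is zero; variability undefined")
    return float(means.std(ddof=1) / mean * 100.0)


def voxel_noise(background_masks: Sequence[Mask], img: Image3D) -> float:
    """Voxel noise (%): coefficient of variation of voxel values pooled
    over the background ROIs of one sphere size."""
    if not background_masks:
        raise GeometryError("no background masks supplied")
    voxels = np.concatenate([m.values_in(img) for m in background_masks])
    if voxels.size < 2:
        raise GeometryError("pooled background voxel count must be >= 2")
    mean = voxels.mean()
    if mean == 0:
        raise InvalidSpecError("background voxel mean is zero; noise undefined")
    return float(voxels.std(ddof=1) / mean * 100.0)


# ---------------------------------------------------------------------------
# Pipeline measurement
# ---------------------------------------------------------------------------
#
# ROI value extraction below works with compact in-plane index arrays
# rather than full-grid boolean masks: the 60-per-size background grid
# on a fine reconstruction grid would otherwise allocate hundreds of
# full-volume arrays. Membership is identical to the Mask-based
# rasterizers (voxel-center inclusion).


def _inplane_indices(
    grid: GridSpec, center: tuple[float, float], radius: float
) -> tuple[np.ndarray, np.ndarray]:
    xs = grid.axis_coords(0) - center[0]
    ys = grid.axis_coords(1) - center[1]
    inside = xs[:, None] ** 2 + ys[None, :] ** 2 <= radius**2
    ix, iy = np.nonzero(inside)
    if ix.size == 0:
        raise GeometryError(
            f"circular ROI at {center} (r={radius} mm) covers no voxel centers"
        )
    return ix, iy


def _circle_values(img: Image3D, roi, cache: dict | None = None) -> np.ndarray:
    key = (roi.center, roi.diameter)
    if cache is not None and key in cache:
        ix, iy = cache[key]
    else:
        ix, iy = _inplane_indices(img.grid, roi.center, roi.radius)
        if cache is not None:
            cache[key] = (ix, iy)
    if not 0 <= roi.slice_index < img.grid.shape[2]:
        raise GeometryError(f"slice index {roi.slice_index} outside image")
    return img.values[ix, iy, roi.slice_index]


def _voi_values(img: Image3D, voi) -> np.ndarray:
    # bounding-box 3-D voxel-center inclusion
    grid = img.grid
    vsz = np.asarray(grid.voxel_size)
    origin = np.asarray(grid.origin)
    c = np.asarray(voi.center)
    lo = np.clip(np.floor((c - voi.radius - origin) / vsz).astype(int), 0, grid.shape)
    hi = np.clip(np.ceil((c + voi.radius - origin) / vsz).astype(int) + 1, 0, grid.shape)
    if np.any(lo >= hi):
        raise GeometryError(f"spherical VOI at {voi.center} outside image")
    dx = grid.axis_coords(0)[lo[0]:hi[0]] - c[0]
    dy = grid.axis_coords(1)[lo[1]:hi[1]] - c[1]
    dz = grid.axis_coords(2)[lo[2]:hi[2]] - c[2]
    inside = (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
        <= voi.radius**2
    )
    if not inside.any():
        raise GeometryError(f"spherical VOI at {voi.center} covers no voxel centers")
    return img.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][inside]


def _background_values(
    img: Image3D, roi_set: ROISet, diameter: float, cache: dict | None = None
) -> list[np.ndarray]:
    return [
        _circle_values(img, roi, cache) for roi in roi_set.background_rois[diameter]
    ]


def measure_sphere(
    img: Image3D,
    roi_set: ROISet,
    diameter: float,
    mode: str = "single_slice",
    cache: dict | None = None,
) -> SphereMeasurement:
    """ROI statistics for one sphere size on one image.

    ``cache`` (an ordinary dict, shared across calls on the same grid)
    memoizes the in-plane ROI membership indices.
    """
    if mode not in ("single_slice", "spherical_voi"):
        raise InvalidSpecError(f"unknown mode {mode!r}")
    if diameter not in roi_set.sphere_rois:
        raise GeometryError(f"no sphere ROI of diameter {diameter} in ROI set")
    roi, voi = roi_set.sphere_rois[diameter]
    if mode == "single_slice":
        sphere_values = _circle_values(img, roi)
    else:
        sphere_values = _voi_values(img, voi)
    bg_values = _background_values(img, roi_set, diameter, cache)
    bg_means = np.array([v.mean() for v in bg_values])
    pooled = np.concatenate(bg_values)
    return SphereMeasurement(
        c_sphere=float(sphere_values.mean()),
        c_background=float(bg_means.mean()),
        sd_background_means=float(bg_means.std(ddof=1)),
        voxel_sd_background=float(pooled.std(ddof=1)),
        mode=mode,
    )


def analyze_phantom(
    img: Image3D,
    roi_set: ROISet,
    phantom: PhantomSpec,
    mode: str = "single_slice",
    cache: dict | None = None,
    **labels,
) -> pd.DataFrame:
    """Tidy per-sphere metrics table for one phantom image.

    Returns one row per sphere with recovery coefficient, percent
    background variability and voxel noise. Extra keyword arguments
    (e.g. ``scanner="PETMR"``, ``iteration=4``) become constant columns
    for downstream concatenation.
    """
    truth = TruthConcentrations(
        a_hot=phantom.hot_concentration,
        a_background=phantom.background_concentration,
    )
    if cache is None:
        cache = {}
    rows = []
    for s in sorted(phantom.spheres, key=lambda s: s.inner_diameter):
        d = s.inner_diameter
        polarity = "hot" if s.concentration > phantom.background_concentration else "cold"
        m = measure_sphere(img, roi_set, d, mode, cache)
        rc = rc_hot(m, truth) if polarity == "hot" else rc_cold(m)
        pooled = np.concatenate(_background_values(img, roi_set, d, cache))
        rows.append(
            {
                "sphere_diameter_mm": d,
                "polarity": polarity,
                "mode": mode,
                "c_sphere_kbq_ml": m.c_sphere,
                "c_background_kbq_ml": m.c_background,
                "sd_background_means_kbq_ml": m.sd_background_means,
                "rc_pct": rc,
                "bg_variability_pct": m.sd_background_means / m.c_background * 100.0,
                "voxel_noise_pct": m.voxel_sd_background / pooled.mean() * 100.0,
                **labels,
            }
        )
    return pd.DataFrame(rows)


def rc_noise_trajectory(
    images: Sequence[Image3D],
    roi_set: ROISet,
    phantom: PhantomSpec,
    mode: str = "single_slice",
    **labels,
) -> pd.DataFrame:
    """Recovery-versus-noise trajectory over an iteration-indexed image
    series (one metrics row per sphere per image, no smoothing)."""
    if not images:
        raise InvalidSpecError("need at least one image")
    grid = images[0].grid
    for img in images[1:]:
        if img.grid != grid:
            raise InvalidSpecError("all images in a trajectory must share a grid")
    cache: dict = {}
    frames = [
        analyze_phantom(
            img, roi_set, phantom, mode, cache, iteration=i + 1, **labels
        )
        for i, img in enumerate(images)
    ]
    return pd.concat(frames, ignore_index=True)


def voxel_noise_replicates(
    images: Sequence[Image3D],
    roi_set: ROISet,
    diameter: float,
    cache: dict | None = None,
) -> tuple[float, float, list[float]]:
    """Voxel noise computed per replicate, then averaged.

    Returns (mean, sample SD across replicates, per-replicate values).
    Replicates are never pooled at the voxel level: each noise
    realization is summarized on its own, matching how replicated
    low-count acquisitions are reported.
    """
    if cache is None:
        cache = {}
    per_rep = []
    for img in images:
        pooled = np.concatenate(_background_values(img, roi_set, diameter, cache))
        per_rep.append(float(pooled.std(ddof=1) / pooled.mean() * 100.0))
    arr = np.asarray(per_rep)
    sd = float(arr.std(ddof=1)) if len(per_rep) > 1 else 0.0
    return float(arr.mean()), sd, per_rep


# ---------------------------------------------------------------------------
# Line profiles
# ---------------------------------------------------------------------------


def line_profile(
    img: Image3D,
    start: Sequence[float],
    end: Sequence[float],
    injected_activity: float,
) -> LineProfile:
    """Single-voxel-width profile along a world-space segment.

    Samples at the minimum in-plane voxel pitch by nearest-voxel lookup
    (no interpolation) and divides by the injected activity (MBq).
    """
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if injected_activity <= 0:
        raise InvalidSpecError("injected_activity must be > 0")
    length = float(np.linalg.norm(end - start))
    if length == 0:
        raise InvalidSpecError("zero-length profile segment")
    vx, vy, _ = img.grid.voxel_size
    step = min(vx, vy)
    n = int(np.floor(length / step)) + 1
    positions = step * np.arange(n)
    direction = (end - start) / length
    points = start[None, :] + positions[:, None] * direction[None, :]
    idx = img.grid.world_to_index(points)
    shape = np.asarray(img.grid.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise GeometryError("profile segment extends outside the image")
    values = img.values[idx[:, 0], idx[:, 1], idx[:, 2]] / injected_activity
    return LineProfile(
        positions=positions,
        values=values,
        start=tuple(start),
        end=tuple(end),
        injected_activity_mbq=float(injected_activity),
    )


# ---------------------------------------------------------------------------
# Sensitivity unit conversion
# ---------------------------------------------------------------------------


def sensitivity_percent(
    cps_per_kbq: float, source_length: float, normalization_length: float
) -> float:
    """Convert a cps/kBq sensitivity to percent, optionally re-normalized
    to a different line-source length.

    1 kBq = 1000 decays/s, so cps/kBq / 1000 is the detected fraction;
    multiplying by ``source_length / normalization_length`` re-expresses
    a full-length normalization against the in-FOV portion (equal
    lengths give the plain unit conversion). Lengths are in cm.
    """
    if source_length <= 0 or normalization_length <= 0:
        raise InvalidSpecError("lengths must be > 0")
    if cps_per_kbq < 0:
        raise InvalidSpecError("cps_per_kbq must be >= 0")
    return cps_per_kbq / 1000.0 * (source_length / normalization_length) * 100.0
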