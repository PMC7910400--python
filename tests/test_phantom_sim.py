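"""Phantom/TAC simulator tests against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy import ndimage
from scipy.integrate import quad

import petquant as pq
from petquant.errors import InvalidSpecError
from petquant.kinetics import dtbz_raclopride_schedule
from petquant.phantom_sim import (
    FWHM_TO_SIGMA,
    _blurred_disc,
    _blurred_slab,
    analytic_blurred_phantom_value,
)

from conftest import single_sphere_phantom


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "matrix, fov, thickness, expected_xy",
    [
        (256, 356.0, 2.78, 1.391),  # human-protocol reconstruction
        (128, 356.0, 2.78, 2.781),  # phantom-protocol reconstruction
        (100, 100.0, 1.0, 1.0),
    ],
)
def test_build_grid_reproduces_voxel_sizes(matrix, fov, thickness, expected_xy):
    grid = pq.build_grid(matrix, fov, thickness)
    assert round(grid.voxel_size[0], 3) == expected_xy
    assert grid.voxel_size[2] == thickness
    # voxel-center convention: grid centered on the origin
    assert np.isclose(grid.axis_coords(0).mean(), 0.0, atol=1e-9)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(matrix=0, in_plane_fov=100.0, slice_thickness=1.0),
        dict(matrix=64, in_plane_fov=-1.0, slice_thickness=1.0),
        dict(matrix=64, in_plane_fov=100.0, slice_thickness=0.0),
    ],
)
def test_build_grid_rejects_invalid_dimensions(kwargs):
    with pytest.raises(InvalidSpecError):
        pq.build_grid(**kwargs)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def test_rasterize_interior_voxel_and_total_activity(phantom, coarse_grid, coarse_truth):
    # voxel at the center of the largest hot sphere carries the hot value
    hot = max(phantom.spheres, key=lambda s: s.concentration * s.inner_diameter)
    idx = coarse_grid.world_to_index(hot.center)[0]
    assert coarse_truth.values[tuple(idx)] == pytest.approx(phantom.hot_concentration)
    # voxel far outside the cylinder is zero
    assert coarse_truth.values[0, 0, 0] == 0.0
    # total activity matches closed-form cylinder + sphere volumes
    analytic = math.pi * phantom.cylinder_radius**2 * phantom.cylinder_height / 1000.0
    analytic *= phantom.background_concentration
    for s in phantom.spheres:
        analytic += (
            4.0 / 3.0 * math.pi * s.radius**3 / 1000.0
        ) * (s.concentration - phantom.background_concentration)
    assert pq.total_activity(coarse_truth) == pytest.approx(analytic, rel=5e-3)


def test_rasterize_subsample_convergence():
    # recovery-relevant quantities (ROI/VOI means) converge in the
    # subsampling order even though individual boundary voxels retain
    # O(1/subsample) coverage quantization
    from petquant.iq_metrics import _circle_values, _voi_values
    from petquant.roi_geometry import CircularROI, SphericalVOI

    ph = single_sphere_phantom()
    grid = pq.build_grid((36, 36, 36), 72.0, 2.0)
    a = pq.rasterize_phantom(ph, grid, subsample=8)
    b = pq.rasterize_phantom(ph, grid, subsample=16)
    center_slice = int(np.argmin(np.abs(grid.axis_coords(2))))
    roi = CircularROI((0.0, 0.0), 19.8, center_slice)
    voi = SphericalVOI((0.0, 0.0, 0.0), 19.8)
    for extract in (
        lambda img: _circle_values(img, roi).mean(),
        lambda img: _voi_values(img, voi).mean(),
        pq.total_activity,
    ):
        assert abs(extract(a) - extract(b)) / abs(extract(b)) < 2e-3


def test_rasterize_clips_out_of_grid_sphere_with_warning():
    ph = pq.PhantomSpec(
        cylinder_radius=60.0,
        cylinder_height=220.0,
        background_concentration=1.0,
        spheres=(pq.SphereSpec((0.0, 0.0, 95.0), 20.0, 2.0),),
        contrast_ratio=2.0,
    )
    grid = pq.build_grid((32, 32, 20), 128.0, 4.0)  # z extent +-38 mm
    with pytest.warns(UserWarning, match="clipped"):
        img = pq.rasterize_phantom(ph, grid, subsample=2)
    assert np.all(np.isfinite(img.values))


# ---------------------------------------------------------------------------
# PSF
# ---------------------------------------------------------------------------


def test_apply_psf_identity_and_validation(coarse_truth):
    out = pq.apply_psf(coarse_truth, 0.0)
    assert np.array_equal(out.values, coarse_truth.values)
    with pytest.raises(InvalidSpecError):
        pq.apply_psf(coarse_truth, -1.0)


def test_apply_psf_conserves_activity(coarse_truth):
    blurred = pq.apply_psf(coarse_truth, 6.0)
    assert pq.total_activity(blurred) == pytest.approx(
        pq.total_activity(coarse_truth), rel=1e-6
    )


def test_apply_psf_impulse_has_nominal_fwhm():
    grid = pq.build_grid((61, 61, 61), 61.0, 1.0)
    values = np.zeros(grid.shape)
    values[30, 30, 30] = 1.0
    blurred = pq.apply_psf(pq.Image3D(values, grid), 5.0)
    # second-moment estimate of sigma along x
    x = grid.axis_coords(0)
    profile = blurred.values.sum(axis=(1, 2))
    sigma = math.sqrt(np.sum(profile * x**2) / profile.sum())
    measured_fwhm = sigma / FWHM_TO_SIGMA
    assert abs(measured_fwhm - 5.0) < 1.0  # within one voxel


def test_apply_psf_center_value_monotone_in_fwhm(small_sphere_image):
    ph, grid, img, _ = small_sphere_image
    centers = []
    for fwhm in (2.0, 4.0, 6.0):
        b = pq.apply_psf(img, fwhm)
        centers.append(b.values[36, 36, 36])
    assert centers[0] > centers[1] > centers[2]


# ---------------------------------------------------------------------------
# Analytic oracles
# ---------------------------------------------------------------------------


def test_analytic_center_value_limits():
    assert pq.analytic_center_value(5.0, 7.7, 0.0) == 7.7
    assert pq.analytic_center_value(500.0, 7.7, 1.0) == pytest.approx(7.7, rel=1e-9)


def test_analytic_center_value_matches_radial_quadrature():
    # independent oracle: integrate the 3-D Gaussian over the ball in
    # spherical coordinates
    R, sigma = 5.0, 2.0
    num = quad(
        lambda r: 4.0
        * math.pi
        * r**2
        * (2.0 * math.pi * sigma**2) ** -1.5
        * math.exp(-(r**2) / (2.0 * sigma**2)),
        0.0,
        R,
    )[0]
    assert pq.analytic_center_value(R, 1.0, sigma) == pytest.approx(num, rel=1e-3)


def test_analytic_sphere_profile_matches_numerical_convolution():
    # direct numerical 3-D convolution of the voxelized indicator
    R, sigma = 8.0, 2.5
    grid = pq.build_grid((96, 96, 96), 48.0, 0.5)
    ph = pq.PhantomSpec(
        cylinder_radius=23.0,
        cylinder_height=46.0,
        background_concentration=1e-12,  # isolate the sphere term
        spheres=(pq.SphereSpec((0.0, 0.0, 0.0), 2 * R, 1.0),),
        contrast_ratio=1.0 / 1e-12,
    )
    img = pq.rasterize_phantom(ph, grid, subsample=4)
    blurred = ndimage.gaussian_filter(
        img.values, sigma / 0.5, mode="constant", truncate=6.0
    )
    x = grid.axis_coords(0)
    for r in (0.0, 4.0, 8.0, 12.0):
        ix = int(np.argmin(np.abs(x - r)))
        numeric = blurred[ix, 48, 48]
        analytic = float(pq.analytic_sphere_profile(abs(x[ix]), R, sigma))
        assert analytic == pytest.approx(numeric, abs=5e-3)


def test_blurred_cylinder_closed_form_matches_numerical_convolution():
    # blurred disc (ncx2) x blurred slab (erf) against gaussian_filter of
    # the voxelized cylinder
    sigma = 2.5
    grid = pq.build_grid((80, 80, 80), 80.0, 1.0)
    ph = pq.PhantomSpec(
        cylinder_radius=25.0,
        cylinder_height=50.0,
        background_concentration=1.0,
        spheres=(),
        contrast_ratio=1.0,
    )
    img = pq.rasterize_phantom(ph, grid, subsample=4)
    blurred = ndimage.gaussian_filter(img.values, sigma, mode="constant", truncate=6.0)
    # evaluate the closed form at exact voxel-center coordinates
    coords = [grid.axis_coords(i) for i in range(3)]
    targets = [(0.0, 0.0, 0.0), (24.0, 0.0, 0.0), (26.0, 0.0, 0.0),
               (0.0, 0.0, 24.0), (20.0, 0.0, 20.0)]
    for t in targets:
        idx = tuple(int(np.argmin(np.abs(coords[i] - t[i]))) for i in range(3))
        pt = np.array([[coords[i][idx[i]] for i in range(3)]])
        expected = analytic_blurred_phantom_value(pt, ph, sigma)[0]
        assert blurred[idx] == pytest.approx(expected, abs=5e-3)
    # factorization sanity: disc and slab each in [0, 1]
    assert 0.0 <= _blurred_disc(np.array([25.0]), 25.0, sigma)[0] <= 1.0
    assert _blurred_slab(np.array([0.0]), 25.0, sigma)[0] == pytest.approx(1.0, abs=1e-9)


def test_blurred_sphere_center_matches_analytic(small_sphere_image):
    ph, grid, img, blurred = small_sphere_image
    s = ph.spheres[0]
    sigma = 5.0 * FWHM_TO_SIGMA
    expected = pq.analytic_blurred_phantom_value(
        np.array([[0.0, 0.0, 0.0]]), ph, sigma
    )[0]
    assert blurred.values[36, 36, 36] == pytest.approx(expected, rel=1e-2)


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------


def test_add_noise_is_seed_reproducible(coarse_blurred):
    model = pq.NoiseModel(target_prompts=1.35e8, seed=42)
    a = pq.add_noise(coarse_blurred, model)
    b = pq.add_noise(coarse_blurred, model)
    assert np.array_equal(a.values, b.values)
    c = pq.add_noise(coarse_blurred, pq.NoiseModel(target_prompts=1.35e8, seed=43))
    assert not np.array_equal(a.values, c.values)


def test_add_noise_mean_and_prompt_scaling():
    grid = pq.build_grid((20, 20, 20), 20.0, 1.0)
    img = pq.Image3D(np.full(grid.shape, 4.3), grid)
    sds = {}
    means = []
    for prompts in (1.2e7, 4.8e7):
        reps = []
        for seed in range(500):
            noisy = pq.add_noise(img, pq.NoiseModel(target_prompts=prompts, seed=seed))
            reps.append(noisy.values)
        reps = np.stack(reps)
        means.append(reps.mean())
        sds[prompts] = reps.std()
    # CLT: mean of a uniform region within 3 SE of truth
    n_total = 500 * 20**3
    sigma_vox = pq.NoiseModel(target_prompts=1.2e7, seed=0).sigma(np.array([4.3]))[0]
    assert abs(means[0] - 4.3) < 3 * sigma_vox / math.sqrt(n_total)
    # quadrupling prompts halves the SD
    assert sds[4.8e7] / sds[1.2e7] == pytest.approx(0.5, rel=0.1)


# ---------------------------------------------------------------------------
# Kinetic forward models
# ---------------------------------------------------------------------------


def test_reference_tac_shape_and_sampling():
    sched = dtbz_raclopride_schedule()
    zero = pq.simulate_reference_tac(sched, amplitude=0.0)
    assert np.all(zero.values == 0.0)

    ref = pq.simulate_reference_tac(sched, amplitude=9.0, alpha=2.0, beta=2.0)
    t_s, y = ref.fine
    # continuous curve peaks at alpha * beta minutes
    assert t_s[np.argmax(y)] / 60.0 == pytest.approx(4.0, abs=0.1)
    # frame averages track midpoint samples within 2 % for the 60 s
    # frames past the initial rise (long late frames of a decaying
    # curve legitimately diverge from their midpoint sample)
    mids_min = sched.mid_times / 60.0
    midpoint = 9.0 * mids_min**2 * np.exp(-mids_min / 2.0)
    smooth = (np.asarray(sched.durations) == 60.0) & (mids_min >= 1.0)
    rel = np.abs(ref.values[smooth] - midpoint[smooth]) / midpoint[smooth]
    assert smooth.sum() == 3 and np.max(rel) < 0.02


def test_srtm_identity_and_r1_scaling():
    sched = dtbz_raclopride_schedule()
    ref = pq.simulate_reference_tac(sched)
    same = pq.simulate_srtm_tac(ref, 1.0, 0.1, 0.0)
    assert np.max(np.abs(same.values - ref.values)) / ref.values.max() < 5e-3

    t1 = pq.simulate_srtm_tac(ref, 1.0, 0.1, 2.0)
    t2 = pq.simulate_srtm_tac(ref, 2.0, 0.1, 2.0)
    assert t2.values[0] / t1.values[0] == pytest.approx(2.0, rel=0.05)

    with pytest.raises(InvalidSpecError):
        pq.simulate_srtm_tac(ref, 0.0, 0.1, 1.0)
    with pytest.raises(InvalidSpecError):
        pq.simulate_srtm_tac(ref, 1.0, 0.1, -0.5)


def test_add_tac_noise_reproducible():
    sched = dtbz_raclopride_schedule()
    ref = pq.simulate_reference_tac(sched)
    a = pq.add_tac_noise(ref, 0.05, 11)
    b = pq.add_tac_noise(ref, 0.05, 11)
    assert np.array_equal(a.values, b.values)


# ---------------------------------------------------------------------------
# Dynamic rendering
# ---------------------------------------------------------------------------


def _two_region_setup():
    sched = dtbz_raclopride_schedule()
    grid = pq.build_grid((12, 12, 6), 24.0, 2.0)
    m1 = np.zeros(grid.shape, dtype=bool)
    m2 = np.zeros(grid.shape, dtype=bool)
    m1[2:5, 2:5, 2:4] = True
    m2[7:10, 7:10, 2:4] = True
    ref = pq.simulate_reference_tac(sched)
    tgt = pq.simulate_srtm_tac(ref, 1.0, 0.1, 2.0)
    return sched, grid, m1, m2, ref, tgt


def test_render_dynamic_roundtrip_and_validation():
    sched, grid, m1, m2, ref, tgt = _two_region_setup()
    img4d = pq.render_dynamic_image([m1, m2], [ref, tgt], grid, sched)
    from petquant.kinetics import extract_tacs

    tacs = extract_tacs(img4d, {"a": m1, "b": m2})
    assert np.allclose(tacs["a"].values, ref.values)
    assert np.allclose(tacs["b"].values, tgt.values)

    overlapping = m1.copy()
    overlapping[7, 7, 2] = True  # intersects m2
    with pytest.raises(InvalidSpecError, match="overlap"):
        pq.render_dynamic_image([overlapping, m2], [ref, tgt], grid, sched)
    with pytest.raises(InvalidSpecError, match="counts"):
        pq.render_dynamic_image([m1], [ref, tgt], grid, sched)


def test_render_dynamic_noise_averages_down_with_roi_size():
    # SD of the noisy ROI mean over replicates ~ sigma_voxel / sqrt(n)
    sched, grid, m1, m2, ref, tgt = _two_region_setup()
    n = int(m1.sum())
    frame = 10  # a late frame with a stable value
    truth = ref.values[frame]
    sigma_vox = pq.NoiseModel(target_prompts=1.2e7, seed=0).sigma(np.array([truth]))[0]
    means = []
    for seed in range(200):
        model = pq.NoiseModel(target_prompts=1.2e7, seed=seed)
        img4d = pq.render_dynamic_image([m1, m2], [ref, tgt], grid, sched, noise=model)
        means.append(img4d.values[m1, frame].mean())
    assert np.std(means, ddof=1) == pytest.approx(sigma_vox / math.sqrt(n), rel=0.2)
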