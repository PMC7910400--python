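import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import petquant as pq

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def phantom():
    """Default six-sphere contrast phantom (3.88:1, two cold spheres)."""
    return pq.contrast_phantom()


@pytest.fixture(scope="session")
def coarse_grid():
    """Phantom-protocol-like grid at a size that rasterizes in seconds."""
    return pq.build_grid((96, 96, 89), 270.0, 2.78)


@pytest.fixture(scope="session")
def coarse_truth(phantom, coarse_grid):
    return pq.rasterize_phantom(phantom, coarse_grid, subsample=4)


@pytest.fixture(scope="session")
def coarse_blurred(coarse_truth):
    return pq.apply_psf(coarse_truth, 6.0)


@pytest.fixture(scope="session")
def coarse_roi_set(coarse_blurred, phantom):
    return pq.build_roi_set(coarse_blurred, phantom)


@pytest.fixture(scope="session")
def fine_truth(phantom):
    """Noiseless phantom on a fine (1.22 mm) reconstruction grid."""
    grid = pq.build_grid((256, 256, 207), 312.32, 1.22)
    return grid, pq.rasterize_phantom(phantom, grid, subsample=4)


def single_sphere_phantom(diameter=19.8, contrast=3.88, background=4.3):
    """One hot sphere centered in a small warm cylinder."""
    return pq.PhantomSpec(
        cylinder_radius=35.0,
        cylinder_height=70.0,
        background_concentration=background,
        spheres=(pq.SphereSpec((0.0, 0.0, 0.0), diameter, contrast * background),),
        contrast_ratio=contrast,
    )


@pytest.fixture(scope="session")
def small_sphere_image():
    """Finely sampled single hot sphere, noiseless and blurred."""
    grid = pq.build_grid((72, 72, 72), 72.0, 1.0)
    ph = single_sphere_phantom()
    img = pq.rasterize_phantom(ph, grid, subsample=4)
    return ph, grid, img, pq.apply_psf(img, 5.0)
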