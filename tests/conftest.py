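import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from y90dose.grid import CountImage, ImageGrid, Mask

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def small_grid():
    return ImageGrid((12, 12, 12), (4.0, 4.0, 4.0))


@pytest.fixture
def unit_grid():
    """1 mL voxels: volumes in mL equal voxel counts."""
    return ImageGrid((16, 16, 16), (10.0, 10.0, 10.0))


def ball_mask(grid, center_vox, radius_vox, name="ball"):
    idx = np.indices(grid.shape)
    d2 = sum((idx[i] - center_vox[i]) ** 2 for i in range(3))
    return Mask(grid, d2 <= radius_vox ** 2, name=name)


def box_mask(grid, lo, hi, name="box"):
    data = np.zeros(grid.shape, dtype=bool)
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return Mask(grid, data, name=name)


@pytest.fixture
def random_masks(small_grid):
    rng = np.random.default_rng(42)
    return [Mask(small_grid, rng.random(small_grid.shape) < p, name=f"m{p}")
            for p in (0.2, 0.5, 0.8)]


@pytest.fixture(scope="session")
def ideal_phantom():
    """Undegraded phantom: no blur, no noise, no shift."""
    from y90dose.phantom import PhantomSpec, generate_phantom
    spec = PhantomSpec(psf_fwhm_mm=0.0, poisson_noise=False,
                       breathing_shift_voxels=0)
    return generate_phantom(spec)
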