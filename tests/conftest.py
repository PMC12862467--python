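import numpy as np
import pytest

from omrad.image_io import MaskVolume, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_ball(radius_mm: float, spacing: float = 1.0, pad: int = 3) -> MaskVolume:
    """Digital ball: voxel centres within radius_mm of the centre."""
    r_vox = radius_mm / spacing
    half = int(np.ceil(r_vox)) + pad
    x, y, z = np.ogrid[-half : half + 1, -half : half + 1, -half : half + 1]
    return MaskVolume((x * x + y * y + z * z) <= r_vox**2, spacing=(spacing,) * 3)


def make_ellipsoid(semi_axes_mm, spacing: float = 1.0, pad: int = 3) -> MaskVolume:
    a, b, c = (s / spacing for s in semi_axes_mm)
    half = int(np.ceil(max(a, b, c))) + pad
    x, y, z = np.ogrid[-half : half + 1, -half : half + 1, -half : half + 1]
    return MaskVolume(
        (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0, spacing=(spacing,) * 3
    )


def random_region(rng, shape=(8, 8, 8), density=0.7, mean=100.0, sd=30.0):
    """A random volume/mask pair for oracle comparisons."""
    vox = rng.normal(mean, sd, size=shape)
    m = rng.random(shape) < density
    m.flat[0] = True  # never empty
    return VolumeGrid(vox), MaskVolume(m)


@pytest.fixture(scope="session")
def small_cohort():
    """One shared 30-patient phantom cohort (default planted band)."""
    from omrad.phantom import PhantomTruth, generate_cohort

    return generate_cohort(30, PhantomTruth(), seed=1234)
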