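import numpy as np
import pytest

from picdl.geometry import Image2D, parallel_geometry
from picdl.polysim import attenuation_image, make_phantom, toy_spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_geom():
    """16x16 grid, 12 parallel views — small enough for exhaustive checks."""
    return parallel_geometry(16, pixel_size=1.0, angles=np.linspace(0, 360, 12, endpoint=False))


@pytest.fixture
def micro_geom():
    """6x6 grid, 8 views — dense-matrix oracle scale."""
    return parallel_geometry(6, pixel_size=1.0, angles=np.linspace(0, 360, 8, endpoint=False))


@pytest.fixture(scope="session")
def shell_setup():
    """128x128 shell phantom with its clean monochromatic target."""
    n, ps = 128, 0.5
    ph = make_phantom("shell_skull", n, ps, seed=0)
    target = attenuation_image(ph, toy_spectrum(1), 0)
    return ph, target, parallel_geometry(n, ps)


def disk_image(n: int, pixel_size: float, radius_mm: float, value: float) -> Image2D:
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = ((xx - c) * pixel_size) ** 2 + ((yy - c) * pixel_size) ** 2
    return Image2D(np.where(r2 <= radius_mm**2, value, 0.0), pixel_size)
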