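import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import ndimage

from cartopo import HeightMap

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def smooth_surface():
    """Factory for a broadband but band-limited random surface."""

    def _make(seed: int, n: int = 128, sigma: float = 2.0, step: float = 1.0) -> HeightMap:
        rng = np.random.default_rng(seed)
        z = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma)
        return HeightMap(z, step=step)

    return _make


@pytest.fixture
def d4_symmetric_surface(smooth_surface):
    """Factory for a surface invariant under the full square symmetry group.

    Averaging a random field over the 4 rotations and the transpose makes
    the spectrum symmetric under 90° rotation and under swapping x/y, so the
    two angular sectors are statistically equivalent.
    """

    def _make(seed: int, n: int = 128) -> HeightMap:
        z = smooth_surface(seed, n=n).heights
        sym = np.zeros_like(z)
        for k in range(4):
            r = np.rot90(z, k)
            sym += r + r.T
        return HeightMap(sym / 8.0)

    return _make
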