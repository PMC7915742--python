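import numpy as np
import pytest

from radrep.grid import GridImage
from radrep.phantom import PhantomSpec, simulate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_spec():
    """Piecewise-constant phantom: no texture, no PSF blur."""
    return PhantomSpec(
        shape=(48, 48, 48),
        spacing=(2.0, 2.0, 2.0),
        background_uptake=1.0,
        tumor_center=(66.0, 47.0, 47.0),
        tumor_radius=12.0,
        tbr_contrast=2.0,
        texture_scale=6.0,
        texture_amplitude=0.0,
        psf_fwhm=0.0,
        exposure=400.0,
    )


@pytest.fixture(scope="session")
def textured_spec():
    return PhantomSpec(
        shape=(48, 48, 48),
        spacing=(2.0, 2.0, 2.0),
        tumor_center=(66.0, 47.0, 47.0),
        tumor_radius=12.0,
        tbr_contrast=2.0,
        texture_amplitude=0.25,
        psf_fwhm=4.0,
        exposure=400.0,
    )


@pytest.fixture(scope="session")
def small_pair(textured_spec):
    """One simulated test/retest pair on a small grid (session-cached)."""
    activity, test, retest = simulate_pair(textured_spec, seed=7)
    return activity, test, retest


@pytest.fixture
def uniform_image():
    return GridImage(np.full((12, 12, 12), 3.0), spacing=(2.0, 2.0, 2.0), unit="SUV")


def random_discretized(rng, max_side=8, ng_max=6):
    """Random small DiscretizedVOI for oracle-equivalence tests."""
    from radrep.features.discretize import DiscretizedVOI

    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[0] = True
    ng = int(rng.integers(1, ng_max + 1))
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    ng = max(int(levels.max()), 1)
    edges = np.arange(ng + 1, dtype=float)
    return DiscretizedVOI(levels=levels, mask=mask, bin_width=1.0, bin_edges=edges, ng=ng)
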