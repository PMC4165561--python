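import numpy as np
import pytest

from fuseseg.synthetic import make_initial_region, make_scene


@pytest.fixture(scope="session")
def scene7():
    """The bias-field disk scene used for segmentation-quality checks."""
    return make_scene(seed=7)


@pytest.fixture(scope="session")
def clean_disk():
    """Two-phase disk with no bias and no noise."""
    return make_scene(bias_strength=0.0, noise_sigma=0.0, seed=7)


@pytest.fixture(scope="session")
def straddle7(scene7):
    return make_initial_region(scene7, "straddling", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def two_phase(n: int, radius: float, fg: float = 180.0, bg: float = 70.0) -> np.ndarray:
    """Clean disk image of side n, centered."""
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2.0
    return np.where((rr - c) ** 2 + (cc - c) ** 2 <= radius**2, fg, bg)


def circle_sdf(n: int, radius: float) -> np.ndarray:
    """Signed distance to a centered circle, negative inside."""
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    c = (n - 1) / 2.0
    return np.sqrt((rr - c) ** 2 + (cc - c) ** 2) - radius
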