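import numpy as np
import pytest

from adenoceph.geometry import LandmarkSet
from adenoceph.synth import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    """Synthetic-generator config on a 64 px canvas (fast to render)."""
    return SynthConfig.scaled(64)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg, 12, rng=np.random.default_rng(7))


def random_landmarks(rng, size=200.0):
    """A random valid landmark set with well-separated Ba/Ar and N > 0."""
    while True:
        pts = rng.uniform(0.1 * size, 0.9 * size, size=(4, 2))
        if np.linalg.norm(pts[0] - pts[1]) < 0.05 * size:
            continue
        try:
            lms = LandmarkSet.from_array(pts)
            from adenoceph.geometry import compute_an
            m = compute_an(lms)
            if m.N > 1e-3:
                return lms
        except Exception:
            continue
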