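import numpy as np
import pytest

from sfcoupling import synth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-structure cohort for fast structural checks."""
    spec = synth.CohortSpec(n_subjects=10, n_regions=20, seed=7)
    return synth.generate_cohort(spec)


def smooth_sphere_map(coords: np.ndarray, rng: np.random.Generator,
                      n_bumps: int = 6, length_scale: float = 0.8) -> np.ndarray:
    """Spatially smooth scalar field on unit-sphere coordinates (sum of
    Gaussian bumps at random centers); used as spin-test fixture maps."""
    centers = rng.normal(size=(n_bumps, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    amps = rng.normal(size=n_bumps)
    d2 = np.sum((coords[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    return np.exp(-d2 / (2 * length_scale**2)) @ amps
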