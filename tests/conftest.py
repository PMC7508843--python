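import numpy as np
import pytest

from amdprog.labeling import build_labeled_sequences
from amdprog.synthetic import CapDruse, CohortSpec, PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def hemisphere_phantom():
    """Single hemispherical druse (radius = height = 0.3 mm) at the fovea."""
    spec = PhantomSpec(
        druse_list=[CapDruse((3.0, 3.0), 0.3, 0.3)],
        druse_intensity_sd=0.05,
        noise_sd=0.02,
        seed=11,
    )
    bundle, truth = generate_phantom(spec)
    return bundle, truth


@pytest.fixture(scope="session")
def small_cohort():
    """60-eye planted-hazard cohort for fast labeling / model tests."""
    histories, truth = generate_cohort(CohortSpec(n_eyes=60, seed=5))
    return histories, truth


@pytest.fixture(scope="session")
def small_sequences(small_cohort):
    histories, _ = small_cohort
    sequences, counts = build_labeled_sequences(histories, (3, 6, 9, 12, 15, 18, 21))
    return sequences, counts


def random_mask(rng: np.random.Generator, shape=(12, 12, 8), p=0.2) -> np.ndarray:
    return rng.random(shape) < p
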