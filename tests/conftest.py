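import numpy as np
import pytest

from eomseg.phantom import PhantomSpec, generate_phantom, phantom_cohort
from eomseg.pipeline import preprocess_pair


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six small preprocessed phantoms for cheap training tests."""
    var = {"thickness_sd": {}, "area_sd": {}, "spacing_range": (0.4, 0.4)}
    cohort = phantom_cohort(
        6, base_spec=PhantomSpec(n_slices=12), variability=var, seed=21
    )
    return [preprocess_pair(v, l) for v, l, _ in cohort]


@pytest.fixture(scope="session")
def phantom_triple():
    """One deterministic default phantom (volume, labels, truth)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noise-free phantom for exact-intensity checks."""
    return generate_phantom(PhantomSpec(seed=7, noise_sd_hu=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
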