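import numpy as np
import pytest

from wavradiomics.synthetic_data import PhantomSpec, make_phantom_case


@pytest.fixture(scope="session")
def small_phantom_spec() -> PhantomSpec:
    """A compact phantom that still clears the 5 mm minimum diameter."""
    return PhantomSpec(grid_shape=(24, 24, 16),
                       lesion_semiaxes_mm=(4.5, 4.0, 3.5))


@pytest.fixture(scope="session")
def phantom_case(small_phantom_spec):
    """One positive-class phantom shared by read-only tests."""
    return make_phantom_case(small_phantom_spec, class_label=1, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
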