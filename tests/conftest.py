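import numpy as np
import pytest

from rembody.cohort_data import load_cohort
from rembody.phantom import PhantomSpec, Sphere, generate_phantom


@pytest.fixture(scope="session")
def cohort():
    """The packaged 24-patient planning cohort."""
    return load_cohort("builtin")


@pytest.fixture(scope="session")
def small_phantom():
    """Liver-only phantom on a coarse grid, no blur, no noise."""
    spec = PhantomSpec(
        shape=(32, 32, 32),
        spacing_mm=(4.0, 4.0, 4.0),
        liver_center_mm=(64.0, 64.0, 48.0),
        liver_semiaxes_mm=(40.0, 36.0, 28.0),
        lung_z_mm=(104.0, 124.0),
        shunt_fraction=0.069,
        seed=7,
    )
    return spec, generate_phantom(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
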