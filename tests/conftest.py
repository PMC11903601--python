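import numpy as np
import pytest

from ufrad.schedules import standard_schedule, ultrafast_schedule
from ufrad.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def uf_schedule():
    return ultrafast_schedule()


@pytest.fixture(scope="session")
def std_schedule():
    return standard_schedule()


@pytest.fixture(scope="session")
def phantom():
    """Default paired phantom with 2% noise."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomSpec(seed=2, noise_sd=0.0))


@pytest.fixture(scope="session")
def small_phantom():
    """Quarter-size grid for cheap pipeline tests."""
    spec = PhantomSpec(
        grid_shape=(16, 32, 32),
        tumor_center_mm=(8.0, 11.0, 11.0),
        tumor_radii_mm=(4.0, 5.0, 5.0),
        aorta_center_mm=(25.0, 25.0),
        aorta_radius_mm=2.5,
        seed=3,
    )
    return generate_phantom(spec)
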