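import numpy as np
import pytest

from iodose import (
    AcquisitionSpec,
    OrganSpec,
    PhantomSpec,
    make_phantom,
)

LN2 = float(np.log(2))


@pytest.fixture(scope="session")
def two_organ_spec():
    """A small two-organ phantom: a 12-mm-radius 'neck' sphere and a
    salivary-like ellipsoid, 2-mm grid, well inside the volume."""
    return PhantomSpec(
        shape=(40, 40, 40),
        spacing_mm=(2.0, 2.0, 2.0),
        organs=[
            OrganSpec("neck_uptake", "sphere", (40, 40, 26), (12, 12, 12), 0.1, 24.0),
            OrganSpec("salivary_glands", "ellipsoid", (40, 40, 56), (14, 10, 8), 0.05, 9.3),
        ],
    )


@pytest.fixture(scope="session")
def two_organ_phantom(two_organ_spec):
    return make_phantom(two_organ_spec)


@pytest.fixture()
def noise_free_acq():
    return AcquisitionSpec(times_h=(24.0, 48.0), calibration_factor_cps_per_mbq=5000.0)
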