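import numpy as np
import pytest

import natriq as nq


@pytest.fixture(scope="session")
def small_phantom():
    """A 40^3 default-concentration phantom shared by unit tests."""
    return nq.build_phantom(nq.PhantomSpec(seed=7, grid_shape=(40, 40, 40)))


@pytest.fixture(scope="session")
def patient_phantom():
    """A 64^3 phantom at the patient-group mean concentrations."""
    return nq.build_phantom(
        nq.PhantomSpec(seed=11, grid_shape=(64, 64, 64), c_gm=34.4, c_wm=30.0)
    )


@pytest.fixture(scope="session")
def psf_kernel():
    return nq.gaussian_psf_kernel(2.65)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
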