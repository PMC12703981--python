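import warnings

import numpy as np
import pytest

from ferromap.grids import AcquisitionParams
from ferromap.phantom import build_phantom, default_phantom_spec, simulate_acquisition

warnings.filterwarnings("ignore", message="medi_invert: not converged")


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def small_phantom():
    """32-cube noiseless phantom with labels and ground truth."""
    spec = default_phantom_spec(n=32, snr=1e12, with_background=False)
    return spec, build_phantom(spec)


@pytest.fixture(scope="session")
def small_acquisition(small_phantom, acq):
    spec, gt = small_phantom
    return simulate_acquisition(gt, acq, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240601)
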