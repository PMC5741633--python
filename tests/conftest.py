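import numpy as np
import pytest

from vesiclefill import synthgen
from vesiclefill.clophensor import ClopHCalibration
from vesiclefill.protocol import make_protocol


@pytest.fixture(scope="session")
def protocol():
    """200 APs at 20 Hz, acquired at 5 Hz, no quench."""
    return make_protocol(5.0, 200, 20.0)


@pytest.fixture(scope="session")
def quench_protocol():
    """Same stimulation with the acid quench starting at stimulation end."""
    return make_protocol(5.0, 200, 20.0, quench=True)


@pytest.fixture(scope="session")
def cal_truth():
    return ClopHCalibration()


@pytest.fixture()
def kinetics_default():
    return {"glutamatergic": synthgen.KineticParams(tau_s=4.9)}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
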