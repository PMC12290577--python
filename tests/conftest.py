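import numpy as np
import pytest

from cthperf.deconv import AcquisitionParams, Aif
from cthperf.oxygen import OxygenTransportParams, calibrate_k
from cthperf.phantom import AifParams, make_aif


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    from cthperf.phantom import DEFAULT_ACQ

    return DEFAULT_ACQ


@pytest.fixture(scope="session")
def aif(acq) -> Aif:
    times = np.arange(100) * acq.dt
    return make_aif(AifParams(), times)


@pytest.fixture(scope="session")
def oxy_params() -> OxygenTransportParams:
    """Transport constants with the wall transfer rate calibrated once."""
    base = OxygenTransportParams()
    from dataclasses import replace

    return replace(base, k_rate=calibrate_k(p=base))
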