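import numpy as np
import pytest

from cvrasl.core import AslAcquisitionParams
from cvrasl.synthdata import (BreathingProtocol, GeometrySpec,
                              generate_bold_phantom, generate_label_map,
                              generate_petco2_trace, make_truth)


@pytest.fixture(scope="session")
def protocol():
    return BreathingProtocol()


@pytest.fixture(scope="session")
def trace(protocol):
    """Noise-free protocol trace on a grid commensurate with TR = 1.05 s."""
    return generate_petco2_trace(protocol, dt=0.05, noise_sd=0.0)


@pytest.fixture(scope="session")
def labels():
    return generate_label_map((12, 12, 5), GeometrySpec(), seed=3)


@pytest.fixture(scope="session")
def truth(labels):
    """Noise-free ground truth with lags on the TR grid (exact recovery)."""
    return make_truth(labels, seed=1, lag_on_tr_grid=1.05)


@pytest.fixture(scope="session")
def bold(truth, trace, protocol):
    return generate_bold_phantom(truth, trace,
                                 baseline_petco2=protocol.baseline_petco2)


@pytest.fixture(scope="session")
def asl_params():
    return AslAcquisitionParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
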