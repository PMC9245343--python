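import numpy as np
import pytest

from poretrace import (
    PoreTrajectory,
    TransportParams,
    VesicleGeometry,
    initial_concentration,
)


@pytest.fixture(scope="session")
def transport():
    return TransportParams()


@pytest.fixture(scope="session")
def geometry_150():
    return VesicleGeometry(vesicle_radius=150e-9)


@pytest.fixture(scope="session")
def c0_150(transport):
    """Initial concentration for the reference case Q = 1 pC, R_ves = 150 nm."""
    return initial_concentration(1e-12, 150e-9, transport)


@pytest.fixture(scope="session")
def logistic_truth():
    """Canonical sigmoid expansion: 30 nm plateau, midpoint 1 ms, steepness 0.3 ms."""
    t = np.arange(0.0, 6e-3 + 5e-5, 1e-4)
    return PoreTrajectory(t, 30e-9 / (1.0 + np.exp(-(t - 1e-3) / 3e-4)))
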