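import numpy as np
import pytest

from spiketempering.background import BackgroundConfig
from spiketempering.calibration import calibrate_reference
from spiketempering.lif_core import NeuronParams


@pytest.fixture(scope="session")
def cuba_params():
    return NeuronParams.from_preset("cuba")


@pytest.fixture(scope="session")
def coba_params():
    return NeuronParams.from_preset("coba")


@pytest.fixture(scope="session")
def ref_background():
    """Reference background defining T = 1: balanced 2/2 kHz at +-0.5 nA."""
    return BackgroundConfig.constant(2.0, 2.0, 0.5, -0.5)


@pytest.fixture(scope="session")
def ref_calibration(cuba_params, ref_background):
    """Full-protocol reference calibration, shared across the session."""
    return calibrate_reference(
        cuba_params, ref_background, n_points=15, duration=20_000.0, seed=5
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
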