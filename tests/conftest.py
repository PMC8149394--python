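import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def nominal_neuron():
    from hfosnn.snn import NeuronParams

    return NeuronParams()


@pytest.fixture(scope="session")
def nominal_synapse():
    from hfosnn.snn import SynapseParams

    return SynapseParams()


@pytest.fixture(scope="session")
def calibrated_threshold(nominal_neuron, nominal_synapse):
    from hfosnn.snn import calibrate_threshold

    return calibrate_threshold(nominal_neuron, nominal_synapse)


@pytest.fixture(scope="session")
def short_background():
    from hfosnn.synthetic import generate_background

    return generate_background(10.0, fs=2000.0, seed=99, n_channels=2,
                               channel_labels=["a", "b"])
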