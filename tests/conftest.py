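import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epsvnet.drive import InputSpec
from epsvnet.engine import TrialProtocol, run_trial
from epsvnet.model import DEFAULT_NEURON_PARAMS, NeuronParams
from epsvnet.network import NetworkConfig, build_network
from epsvnet.tf import TFGrid

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pc_params() -> NeuronParams:
    return DEFAULT_NEURON_PARAMS["PC"]


@pytest.fixture(scope="session")
def pv_params() -> NeuronParams:
    return DEFAULT_NEURON_PARAMS["PV"]


@pytest.fixture(scope="session")
def lif_params() -> NeuronParams:
    """A pure leaky integrate-and-fire parameter set (hard threshold)."""
    return NeuronParams(
        name="LIF", C_m=190.0, E_L=-70.0, g_L=20.0, V_th=-45.0, V_r=-65.0,
        tau_e=0.5, tau_i=5.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def single_pop_net():
    """Small, weakly coupled purely excitatory circuit."""
    return build_network(NetworkConfig.single_population(n=200), seed=5)


@pytest.fixture(scope="session")
def ei_net():
    """Small two-population E-I circuit."""
    return build_network(NetworkConfig.excitatory_inhibitory(n_exc=320, n_inh=80), seed=6)


@pytest.fixture(scope="session")
def epsv_net():
    """The full default circuit (3600/480/360/360); built once per session."""
    return build_network(NetworkConfig.default(), seed=42)


@pytest.fixture(scope="session")
def baseline_record(epsv_net):
    """One baseline-drive trial of the full circuit with a 2 s scoring window."""
    return run_trial(
        epsv_net, InputSpec(), TrialProtocol.baseline(measure=2000.0), seed=7
    )


@pytest.fixture(scope="session")
def linear_grid() -> TFGrid:
    """Synthetic transfer-function: exactly linear in all three inputs."""
    ax = np.linspace(-8.0, 8.0, 7)
    return TFGrid.from_function(
        (ax, ax, ax),
        {
            "PC": lambda e, p, s: 15.0 + 0.5 * e - 0.35 * p - 0.25 * s,
            "PV": lambda e, p, s: 14.0 + 0.3 * e + 0.4 * p - 0.6 * s,
            "SST": lambda e, p, s: 7.5 + 0.1 * e - 0.05 * p + 0.45 * s,
        },
    )


@pytest.fixture(scope="session")
def smooth_grid() -> TFGrid:
    """Synthetic transfer-function with mild curvature and cross terms."""
    ax = np.linspace(-8.0, 8.0, 9)

    def f_e(e, p, s):
        return (
            13.0 + 0.6 * e - 0.45 * p - 0.3 * s
            + 0.015 * e * e + 0.01 * e * p - 0.008 * p * s
        )

    return TFGrid.from_function(
        (ax, ax, ax),
        {
            "PC": f_e,
            "PV": lambda e, p, s: 14.0 + 0.25 * e + 0.5 * p - 0.4 * s,
            "SST": lambda e, p, s: 8.0 + 0.1 * e + 0.4 * s,
        },
    )
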