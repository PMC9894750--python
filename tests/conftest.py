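import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config_a_trace():
    """One 5 s reference run of the ~5 Hz neuron at 2 uA, shared by tests."""
    from coecn import configs, circuit, stimuli

    p = configs.config_a()
    solver = configs.default_solver("config-a")
    return p, circuit.simulate(p, stimuli.constant(2e-6), 5.0, solver=solver)


@pytest.fixture(scope="session")
def config_b_trace():
    """One 2 s run of the fast (no external capacitor) neuron at 2 uA."""
    from coecn import configs, circuit, stimuli

    p = configs.config_b()
    solver = configs.default_solver("config-b")
    return p, circuit.simulate(p, stimuli.constant(2e-6), 2.0, solver=solver)


@pytest.fixture()
def sawtooth_trace():
    """Synthetic 5 Hz sawtooth crossing 0.25 V, for detector tests."""
    from coecn.circuit import SimulationTrace

    t = np.arange(0.0, 4.0, 1e-4)
    v = 0.1 + 0.3 * ((t * 5.0) % 1.0)
    z = np.zeros_like(t)
    return SimulationTrace(t=t, V_mem=v, V_gk=z, I_in=z, I_Na=z, I_K=z)
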