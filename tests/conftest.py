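import numpy as np
import pytest
from hypothesis import settings

import eipkit as ek
from eipkit.pipeline import RunConfig, simulate_measurement

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def channel():
    return ek.generic_fast_nav()


@pytest.fixture(scope="session")
def protocol():
    return ek.build_seventeen_pulse_protocol()


@pytest.fixture(scope="session")
def control_peaks(channel, protocol):
    """Drug-free control peak amplitudes of one steady sweep."""
    return ek.simulate_sweep(channel, None, protocol).peaks_nA


@pytest.fixture(scope="session")
def state_dep_compound():
    """Strongly state-dependent compound: K_R/K_I = 100, unbinding time
    constant from the inactivated state 1/(k_on*K_I) = 3 ms."""
    return ek.CompoundMechanism(
        name="state_dep", k_on=1.0 / 30.0, K_R=1000.0, K_I=10.0,
        perfusion_tau_s=2.0,
    )


@pytest.fixture(scope="session")
def recovery_config(state_dep_compound):
    return RunConfig(
        mechanism=state_dep_compound,
        concentrations_uM=(3.0, 10.0, 30.0, 100.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def recovery_base(recovery_config):
    """One simulated recovery-scenario experiment; replicate 'ensembles' are
    produced by re-drawing measurement noise on its deterministic peaks."""
    return simulate_measurement(recovery_config)


@pytest.fixture(scope="session")
def ttx_config():
    mech = ek.compound_preset("ttx_like")
    mech.perfusion_tau_s = 2.0  # short perfusion keeps the schedule compact
    return RunConfig(mechanism=mech, concentrations_uM=(0.01, 0.03, 0.1), seed=7)


@pytest.fixture(scope="session")
def ttx_base(ttx_config):
    return simulate_measurement(ttx_config)


@pytest.fixture(scope="session")
def replicate_seeds():
    ss = np.random.SeedSequence(2025).spawn(6)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss]
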