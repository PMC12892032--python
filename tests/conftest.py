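import numpy as np
import pytest

import dyadmrt as d


@pytest.fixture(scope="session")
def design():
    return d.TrialDesign()


@pytest.fixture(scope="session")
def proximal_trial():
    """One simulated trial at study scale with proximal effects on."""
    table, log, params = d.simulate_trial(d.scenario_proximal(seed=20240501))
    return table, log, params


@pytest.fixture(scope="session")
def phase_trial():
    """One simulated trial from the intervention-phase recovery scenario."""
    table, log, params = d.simulate_trial(d.scenario_phase(seed=20240502))
    return table, log, params


@pytest.fixture(scope="session")
def tiny_trial():
    """A 4-couple trial for dense-oracle comparisons."""
    table, log, params = d.simulate_trial(
        d.scenario_phase(seed=99, n_couples=4, miss_device=0.05, miss_self=0.05)
    )
    return table, log, params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
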