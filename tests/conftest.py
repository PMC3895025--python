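import pytest

from dmsbox import default_scenario, generate_forcing, run_simulation, integrate_budget


@pytest.fixture(scope="session")
def default_forcing():
    """Reference-scenario forcing, 15-min step, one full year."""
    blooms, env = default_scenario()
    return generate_forcing(blooms, env, dt=0.25, seed=1)


@pytest.fixture(scope="session")
def default_result(default_forcing):
    return run_simulation(default_forcing)


@pytest.fixture(scope="session")
def default_budget(default_result):
    return integrate_budget(default_result)


@pytest.fixture(scope="session")
def coarse_forcing():
    """Hourly-step forcing for cheaper structural tests."""
    blooms, env = default_scenario()
    return generate_forcing(blooms, env, dt=1.0, seed=1)
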