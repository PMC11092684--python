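import pytest

import savm


@pytest.fixture(scope="session")
def params():
    return savm.ScenarioParams()


@pytest.fixture(scope="session")
def fixture_bundle(params):
    return savm.default_fixture(params)


@pytest.fixture(scope="session")
def derived(fixture_bundle, params):
    """Derived schedules with the packaged calibration adjusters applied."""
    return savm.derive_schedules(fixture_bundle, params, savm.Adjusters.default())


@pytest.fixture(scope="session")
def derived_raw(fixture_bundle, params):
    """Derived schedules with unit adjusters (pre-calibration)."""
    return savm.derive_schedules(fixture_bundle, params, savm.Adjusters.unit())


@pytest.fixture(scope="session")
def restricted_traj(derived, params):
    return savm.run_scenario(derived, params, "restricted")


@pytest.fixture(scope="session")
def unrestricted_traj(derived, params):
    return savm.run_scenario(derived, params, "unrestricted")
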