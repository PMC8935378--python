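import pytest

from cassava_npk import ModelParameters, generate_synthetic_weather
from cassava_npk import engine, treatments


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def wet_weather():
    """One fixed 420-day humid-tropical season without serious drought."""
    return generate_synthetic_weather(seed=1, n_days=420, climate_profile="wet")


@pytest.fixture(scope="session")
def omission_battery(params, wet_weather):
    """Daily outputs for control, the three single omissions and full NPK."""
    scens = treatments.standard_battery(
        supply=treatments.edo_like_supply(),
        treatments=["control", "N0PfKf", "NfP0Kf", "NfPfK0", "NfPfKf"])
    return {name: engine.simulate(params, scen, wet_weather)
            for name, scen in scens.items()}
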