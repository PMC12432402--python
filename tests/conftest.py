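import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fidascreen import simulate
from fidascreen.physics import InstrumentMethod, Taylorgram

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def method() -> InstrumentMethod:
    return InstrumentMethod()


@pytest.fixture()
def clean_trace(method) -> Taylorgram:
    """Noiseless single-species trace at the small-indicator radius."""
    return simulate.simulate_taylorgram(
        method, [simulate.SpeciesState(rh=1.15)], None, 1.0, 50e-9, 0.0, 0)


@pytest.fixture()
def flat_trace(method) -> Taylorgram:
    t = np.linspace(0.0, 180.0, 1801)
    sig = np.zeros_like(t)
    sig[900] = 1.0  # single spike so peak height is defined
    return Taylorgram(time=t, signal=sig, method=method)
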