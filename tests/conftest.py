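import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ddrtgi import DRUGS, Scenario, Treatment, parse_regimen
from ddrtgi.params import DEFAULT_PK

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_arm(tumour, *drugs, horizon=42.0, output_days=None):
    """Scenario for one treatment arm; ``drugs`` are (name, regimen) pairs."""
    treatments = [
        Treatment(DRUGS[name], DEFAULT_PK[name], parse_regimen(expr, drug_id=name))
        for name, expr in drugs
    ]
    return Scenario(tumour, treatments, horizon, output_days)


@pytest.fixture(scope="session")
def arm_factory():
    return make_arm


@pytest.fixture(scope="session")
def hbcx9_study1():
    from ddrtgi import hbcx9

    return hbcx9(1)
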