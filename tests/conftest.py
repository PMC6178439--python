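import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ninocast import GeneratorConfig, MonthlySeries, generate_bundle

settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


def monthly(records, units="ppm"):
    """Shorthand constructor used across the suite."""
    return MonthlySeries.from_records(records, units=units)


def flat_year(year, value):
    """All 12 months of a calendar year at one value."""
    return [(year, m, value) for m in range(1, 13)]


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Closed-loop bundle: increments obey the regression exactly."""
    cfg = GeneratorConfig(seed=11, residual_sd=0.0, member_spread=0.0)
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default study conditions (residual sd 0.25 ppm)."""
    return generate_bundle(GeneratorConfig(seed=3))
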