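import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ipsphen import ClimateSpec, ModelParameters, generate_series

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture()
def constant_weather():
    """Season-long constant weather: I_max = 18.3, I_mean = 13.0, I_min = 7.7.

    The 10 dd/day accumulation makes onset arithmetic hand-checkable."""
    return generate_series(
        ClimateSpec(annual_mean=13.0, annual_amplitude=0.0, diurnal_range=10.6,
                    noise_sd=0.0, year=2019)
    )


def window_series(values, year=2019, month=3, day=7):
    """pd.Series of daily values starting at the model start date."""
    index = pd.date_range(pd.Timestamp(year, month, day), periods=len(values), freq="D")
    return pd.Series(values, index=index, dtype=float)
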