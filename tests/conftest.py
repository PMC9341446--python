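import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import heatrisk as hr

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tokyo_cases() -> pd.DataFrame:
    """Five years of synthetic Tokyo-scale daily cases for all age groups."""
    spec = hr.ClimateScenarioSpec(start_year=2015, end_year=2019, seed=101)
    climate = hr.simulate_climate(spec)
    return hr.simulate_cases(climate, hr.tokyo_like_truth(), seed=202)


@pytest.fixture(scope="session")
def elderly_exp_fit(tokyo_cases) -> hr.FitResult:
    """Exponential-model fit to the synthetic 65+ series (seasonal days)."""
    return hr.fit_model(tokyo_cases, "exponential", age_group="65+")


@pytest.fixture()
def season_year() -> pd.DataFrame:
    """One complete calendar year of constant WBGT 20 °C."""
    dates = pd.date_range("2020-01-01", "2020-12-31", freq="D")
    return pd.DataFrame({"date": dates, "wbgt_c": 20.0})


def constant_wbgt_years(start: int, end: int, value: float) -> pd.DataFrame:
    dates = pd.date_range(f"{start}-01-01", f"{end}-12-31", freq="D")
    return pd.DataFrame({"date": dates, "wbgt_c": value})
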