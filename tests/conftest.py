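import numpy as np
import pandas as pd
import pytest

from orchardphen.phenology_engine import TemperatureSeries
from orchardphen.rate_models import (
    APHELINUS_MALI_DD,
    APHELINUS_MALI_POLY,
    ERIOSOMA_LANIGERUM_DD,
    ERIOSOMA_LANIGERUM_POLY,
)

# printed polynomial coefficients, constant-first (ground truth for fitting)
AMALI_COEFFS = (-2.940e-3, -1.716e-4, 4.895e-4, -5.389e-5, 2.653e-6, -4.303e-8)
ELANIGERUM_COEFFS = (
    1.013e-3, -9.014e-4, -2.011e-4, 1.044e-4, -8.425e-6, 2.731e-7, -3.209e-9,
)


@pytest.fixture
def amali_poly():
    return APHELINUS_MALI_POLY


@pytest.fixture
def elanigerum_poly():
    return ERIOSOMA_LANIGERUM_POLY


@pytest.fixture
def amali_dd():
    return APHELINUS_MALI_DD


@pytest.fixture
def elanigerum_dd():
    return ERIOSOMA_LANIGERUM_DD


def constant_series(temp_c, year=2018, days=365, resolution="daily"):
    """A constant-temperature series starting 1 Jan."""
    if resolution == "daily":
        idx = pd.date_range(f"{year}-01-01", periods=days, freq="D")
    else:
        idx = pd.date_range(f"{year}-01-01", periods=days * 24, freq="h")
    return TemperatureSeries(idx, np.full(len(idx), float(temp_c)), resolution)


@pytest.fixture
def warm_series():
    return constant_series(18.3)


@pytest.fixture
def cold_series():
    return constant_series(4.0)
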