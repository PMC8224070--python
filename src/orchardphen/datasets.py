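"""Loaders for the packaged fixture data.

Ships the published 2010-2020 validation tables (predicted and observed
event dates for parasitoid G1/G2 adult emergence and aphid crawler
migration), the degree-day constants, and the two polynomial rate-model
configurations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .rate_models import RateModel, load_model_config
from .validation_stats import ValidationTable, read_observations

__all__ = [
    "load_amali_observations",
    "load_elanigerum_observations",
    "load_degree_day_constants",
    "load_amali_model",
    "load_elanigerum_model",
    "fixture_path",
]

_DATA = resources.files("orchardphen") / "data"


def fixture_path(name: str):
    """Filesystem path of a packaged fixture file."""
    return _DATA / name


def load_amali_observations() -> dict[str, ValidationTable]:
    """G1/G2 adult-emergence validation tables (11 years), keyed by event."""
    tables = read_observations(fixture_path("amali_observations.csv"))
    return {t.event: t for t in tables}


def load_elanigerum_observations() -> ValidationTable:
    """First-crawler-migration validation table (11 years)."""
    (table,) = read_observations(fixture_path("elanigerum_observations.csv"))
    return table


def load_degree_day_constants() -> pd.DataFrame:
    """Lower thresholds and degree-day requirements per species/stage."""
    return pd.read_csv(fixture_path("degree_days.csv"))


def load_amali_model() -> RateModel:
    """Packaged degree-5 polynomial model for the parasitoid."""
    return load_model_config(fixture_path("amali_polynomial.yaml"))


def load_elanigerum_model() -> RateModel:
    """Packaged degree-6 polynomial model for the woolly apple aphid."""
    return load_model_config(fixture_path("elanigerum_polynomial.yaml"))
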