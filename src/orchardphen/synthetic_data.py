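"""Synthetic weather series and interval-censored monitoring observations.

The temperature generator produces one calendar year of hourly or daily
records as seasonal sine + diurnal sine (hourly only) + AR(1) noise,
emulating the structure of a temperate-climate orchard weather station.
The trap-observation generator censors a true event date through a
periodic check schedule and applies the midpoint convention, mirroring
how first-detection dates are derived from sticky-trap monitoring.
``end_to_end_scenario`` chains weather -> phenology -> censoring into a
multi-year synthetic validation campaign.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .phenology_engine import (
    NOT_REACHED,
    TemperatureSeries,
    forecast_events,
)
from .rate_models import RateModel
from .validation_stats import ValidationRow, ValidationTable, mean_observation_date

__all__ = [
    "ClimateParams",
    "TrapProtocol",
    "generate_temperature_series",
    "generate_trap_observations",
    "end_to_end_scenario",
    "BELGIUM_DEFAULTS",
]


@dataclass(frozen=True)
class ClimateParams:
    """Parameters of the synthetic orchard temperature generator."""

    annual_mean_c: float = 10.5
    seasonal_amplitude_c: float = 7.5
    seasonal_phase_doy: float = 15.0  # day of year of the seasonal minimum
    diurnal_amplitude_c: float = 4.0
    ar_coefficient: float = 0.8
    innovation_sd_c: float = 1.5
    year: int = 2018
    resolution: str = "hourly"

    def __post_init__(self) -> None:
        if self.seasonal_amplitude_c < 0 or self.diurnal_amplitude_c < 0:
            raise ValueError("amplitudes must be >= 0")
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
        if self.innovation_sd_c < 0:
            raise ValueError("innovation sd must be >= 0")
        if self.resolution not in ("hourly", "daily"):
            raise ValueError(f"unknown resolution {self.resolution!r}")


# Sint-Truiden-like defaults: G1 emergence lands in April-early May and
# first crawler migration in April-May, comparable to the monitored range.
BELGIUM_DEFAULTS = ClimateParams()


@dataclass(frozen=True)
class TrapProtocol:
    """Periodic trap-check schedule with exact detection at the first
    check on/after the true event date."""

    check_interval_days: tuple[int, int] = (3, 7)  # inclusive range
    season_start: tuple[int, int] = (4, 1)  # (month, day)
    season_end: tuple[int, int] = (7, 31)
    miss_probability: float = 0.0  # hook; default: detection is perfect

    def __post_init__(self) -> None:
        lo, hi = self.check_interval_days
        if not (1 <= lo <= hi):
            raise ValueError("check interval bounds must satisfy 1 <= lo <= hi")
        if hi > 14:
            raise ValueError("check interval above 14 days is not a plausible protocol")
        if not 0.0 <= self.miss_probability < 1.0:
            raise ValueError("miss probability must be in [0, 1)")


def generate_temperature_series(
    params: ClimateParams, seed: int | None = None
) -> TemperatureSeries:
    """One calendar year of synthetic temperatures, reproducible per seed.

    ``T(t) = mean + seasonal sine + diurnal sine (hourly only) + AR(1)``
    where the seasonal sine bottoms out at ``seasonal_phase_doy`` and the
    diurnal sine peaks mid-afternoon (15:00).
    """
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(year=params.year, month=1, day=1)
    end = pd.Timestamp(year=params.year, month=12, day=31, hour=23)
    if params.resolution == "hourly":
        idx = pd.date_range(start, end, freq="h")
    else:
        idx = pd.date_range(start, end.normalize(), freq="D")
    n = len(idx)

    doy = idx.dayofyear.to_numpy() + idx.hour.to_numpy() / 24.0
    seasonal = -params.seasonal_amplitude_c * np.cos(
        2 * np.pi * (doy - params.seasonal_phase_doy) / 365.25
    )
    temps = params.annual_mean_c + seasonal
    if params.resolution == "hourly":
        hour = idx.hour.to_numpy()
        temps = temps + params.diurnal_amplitude_c * np.sin(
            2 * np.pi * (hour - 9.0) / 24.0
        )

    if params.innovation_sd_c > 0:
        noise = np.empty(n)
        innovations = rng.normal(0.0, params.innovation_sd_c, n)
        # stationary start so early-January noise is not atypical
        noise[0] = innovations[0] / np.sqrt(1 - params.ar_coefficient**2)
        for i in range(1, n):
            noise[i] = params.ar_coefficient * noise[i - 1] + innovations[i]
        temps = temps + noise

    temps = np.clip(temps, -39.9, 54.9)  # stay inside the series validity range
    return TemperatureSeries(
        timestamps=idx, temperatures=temps, resolution=params.resolution
    )


def generate_trap_observations(
    true_event_date: date,
    protocol: TrapProtocol,
    seed: int | None = None,
) -> tuple[date, date, date]:
    """Censor a true event date through a trap-check schedule.

    Check dates start at the season start and advance by the protocol
    interval (drawn uniformly per step when the interval is a range).  The
    event is detected at the first check on/after the true date; returns
    ``(last_negative, first_positive, observed)`` where observed is the
    bracket midpoint rounded toward the earlier day.  The censoring error
    is therefore at most interval/2 + rounding.
    """
    rng = np.random.default_rng(seed)
    season_start = date(true_event_date.year, *protocol.season_start)
    season_end = date(true_event_date.year, *protocol.season_end)
    if not season_start <= true_event_date <= season_end:
        raise ValueError(
            f"true event date {true_event_date} outside the monitoring season "
            f"{season_start}..{season_end}"
        )
    lo, hi = protocol.check_interval_days

    check = season_start
    prev = season_start - timedelta(days=int(rng.integers(lo, hi + 1)))
    while check < true_event_date or (
        protocol.miss_probability > 0
        and check >= true_event_date
        and rng.random() < protocol.miss_probability
    ):
        prev = check
        check = check + timedelta(days=int(rng.integers(lo, hi + 1)))
        if check > season_end + timedelta(days=hi):
            raise ValueError("event was never detected within the season")
    last_negative, first_positive = prev, check
    if (first_positive - last_negative).days == 1:
        # a one-day bracket pinpoints the event exactly at daily granularity
        observed = first_positive
    else:
        observed = mean_observation_date(
            last_negative, first_positive, max_interval_days=2 * hi
        )
    return last_negative, first_positive, observed


def end_to_end_scenario(
    climate: ClimateParams,
    models: dict[str, RateModel],
    protocol: TrapProtocol,
    n_years: int,
    seed: int | None = None,
) -> dict[str, ValidationTable]:
    """Run a synthetic multi-year monitoring campaign.

    For each year: generate weather, run the deterministic phenology
    forecast for every model (the "truth"), censor each event date
    through the trap protocol, and collect per-event validation tables
    keyed ``"<model key>: <event name>"``.  In the synthetic campaign the
    predicted date equals the true date (same weather drives both), so the
    residual error is pure observation censoring.  Years where an event is
    not reached yield NA rows.
    """
    if n_years < 1:
        raise ValueError("need at least one year")
    rng = np.random.default_rng(seed)
    tables: dict[str, list[ValidationRow]] = {}
    for i in range(n_years):
        year_params = replace(climate, year=climate.year + i)
        series = generate_temperature_series(
            year_params, seed=int(rng.integers(0, 2**31))
        )
        for key, model in models.items():
            fc = forecast_events(model, series)
            for name, _threshold, true_date in fc.events:
                label = f"{key}: {name}"
                tables.setdefault(label, [])
                if true_date == NOT_REACHED:
                    row = ValidationRow(year=year_params.year, predicted=None, observed=None)
                else:
                    try:
                        last_neg, first_pos, observed = generate_trap_observations(
                            true_date, protocol, seed=int(rng.integers(0, 2**31))
                        )
                        row = ValidationRow(
                            year=year_params.year,
                            predicted=true_date,
                            observed=observed,
                            last_negative=last_neg,
                            first_positive=first_pos,
                        )
                    except ValueError:
                        row = ValidationRow(
                            year=year_params.year, predicted=true_date, observed=None
                        )
                tables[label].append(row)
    return {
        label: ValidationTable(event=label, rows=tuple(rows))
        for label, rows in tables.items()
    }
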