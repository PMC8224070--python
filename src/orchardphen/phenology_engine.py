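"""Cumulative development over a temperature series and event extraction.

Development accrues from 1 January with an overwintering head start
(``start_fraction`` generations already completed): at each timestep the
clamped development rate (per day) is multiplied by the step length in
days (1/24 for hourly records) and cumulatively summed.  Named events fire
at the first timestamp where cumulative development reaches their
threshold; events never reached within the series are reported as such.

A stochastic cohort variant perturbs the per-timestep rate of each
individual with truncated Gaussian noise, reproducing individual-based
simulation of emergence spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rate_models import RateModel, evaluate_rate

__all__ = [
    "TemperatureSeries",
    "PhenologyForecast",
    "CohortResult",
    "SeriesError",
    "accumulate_development",
    "predict_event_dates",
    "forecast_events",
    "simulate_individuals",
    "stage_fraction_from_ratio",
    "read_temperature_series",
    "write_event_report",
    "NOT_REACHED",
]

NOT_REACHED = "not reached"

# longest gap filled by linear interpolation, per resolution
_MAX_FILL = {"hourly": pd.Timedelta(hours=6), "daily": pd.Timedelta(days=1)}
_STEP = {"hourly": pd.Timedelta(hours=1), "daily": pd.Timedelta(days=1)}


class SeriesError(ValueError):
    """Raised for malformed or gap-ridden temperature series."""


@dataclass(frozen=True)
class TemperatureSeries:
    """Time-ordered (timestamp, deg C) records at hourly or daily resolution."""

    timestamps: pd.DatetimeIndex
    temperatures: np.ndarray
    resolution: str  # "hourly" | "daily"

    def __post_init__(self) -> None:
        if self.resolution not in ("hourly", "daily"):
            raise SeriesError(f"unknown resolution {self.resolution!r}")
        if len(self.timestamps) != len(self.temperatures):
            raise SeriesError("timestamps and temperatures differ in length")
        if len(self.timestamps) < 2:
            raise SeriesError("series needs at least 2 records")
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise SeriesError("timestamps must be strictly increasing")
        temps = np.asarray(self.temperatures, float)
        if np.any(~np.isfinite(temps)) or np.any(temps < -40) or np.any(temps > 55):
            raise SeriesError("temperatures must be finite and within -40..55 degC")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def step_days(self) -> float:
        return 1.0 / 24.0 if self.resolution == "hourly" else 1.0

    @classmethod
    def from_frame(cls, df: pd.DataFrame, resolution: str | None = None) -> "TemperatureSeries":
        """Build a series from a frame with ``timestamp``/``temperature_c``.

        Resolution is auto-detected from the median timestamp spacing when
        not given.  Gaps up to 6 h (hourly) or 1 day (daily) are filled by
        linear interpolation; longer gaps raise :class:`SeriesError`.
        """
        ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
        temps = np.asarray(df["temperature_c"], float)
        order = np.argsort(ts)
        ts, temps = ts[order], temps[order]
        if ts.has_duplicates:
            raise SeriesError("duplicate timestamps")

        if resolution is None:
            median_step = pd.Series(ts).diff().median()
            resolution = "hourly" if median_step <= pd.Timedelta(hours=1) else "daily"

        step = _STEP[resolution]
        gaps = pd.Series(ts).diff().iloc[1:]
        worst = gaps.max()
        if worst > _MAX_FILL[resolution] + step:
            at = ts[int(gaps.idxmax())]
            raise SeriesError(
                f"gap of {worst} at {at} exceeds the fill window for "
                f"{resolution} data"
            )
        if worst > step:
            full = pd.date_range(ts[0], ts[-1], freq=step)
            series = pd.Series(temps, index=ts).reindex(full).interpolate("time")
            ts, temps = full, series.to_numpy()
        return cls(timestamps=ts, temperatures=temps, resolution=resolution)


@dataclass(frozen=True)
class PhenologyForecast:
    """Cumulative-development trajectory plus extracted event dates."""

    species_label: str
    timestamps: pd.DatetimeIndex
    trajectory: np.ndarray  # cumulative development, generation units
    start_fraction: float
    events: tuple[tuple[str, float, date | str], ...] = ()

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps, "cumulative_development": self.trajectory}
        )


@dataclass(frozen=True)
class CohortResult:
    """Per-individual event dates from a stochastic cohort simulation."""

    species_label: str
    event_dates: dict[str, list[date | str]]  # event name -> n dates
    n: int
    sd: float
    seed: int | None

    def summary(self, event: str) -> dict:
        """First/median/quantile dates for one event (reached individuals)."""
        dates = [d for d in self.event_dates[event] if isinstance(d, date)]
        if not dates:
            return {
                "event": event,
                "n_reached": 0,
                "first": NOT_REACHED,
                "median": NOT_REACHED,
                "q10": NOT_REACHED,
                "q90": NOT_REACHED,
            }
        ordinals = np.array([d.toordinal() for d in dates])
        q = np.quantile(ordinals, [0.1, 0.5, 0.9], method="nearest")
        return {
            "event": event,
            "n_reached": len(dates),
            "first": date.fromordinal(int(ordinals.min())),
            "median": date.fromordinal(int(q[1])),
            "q10": date.fromordinal(int(q[0])),
            "q90": date.fromordinal(int(q[2])),
        }


def _check_window(series: TemperatureSeries) -> None:
    first = series.timestamps[0]
    jan1 = pd.Timestamp(year=first.year, month=1, day=1)
    if first > jan1:
        raise SeriesError(
            f"series must start on or before 1 Jan (starts {first.date()})"
        )


def accumulate_development(
    model: RateModel,
    series: TemperatureSeries,
    start_fraction: float | None = None,
) -> PhenologyForecast:
    """Cumulatively sum clamped development over the series.

    ``D(t_k) = start_fraction + sum_{j<=k} rate(T_j) * dt`` with ``dt`` in
    days.  Timesteps outside the model's thermal window contribute exactly
    zero.  ``start_fraction`` defaults to the model's configured value.
    """
    _check_window(series)
    if start_fraction is None:
        start_fraction = model.start_fraction
    if start_fraction < 0:
        raise ValueError("start_fraction must be >= 0")
    rates = evaluate_rate(model, series.temperatures)
    increments = rates * series.step_days
    # the head start is the state at the first timestamp; increment j is
    # the development accrued over the interval ending at timestamp j
    trajectory = start_fraction + np.concatenate(([0.0], np.cumsum(increments[1:])))
    return PhenologyForecast(
        species_label=model.species_label,
        timestamps=series.timestamps,
        trajectory=trajectory,
        start_fraction=start_fraction,
    )


def predict_event_dates(
    forecast: PhenologyForecast,
    event_thresholds: Sequence[tuple[str, float]],
) -> PhenologyForecast:
    """Attach first-crossing event dates to a forecast.

    Each event fires on the calendar date of the first timestamp with
    cumulative development >= its threshold; thresholds must be strictly
    increasing.  Unreached events carry the sentinel ``"not reached"``.
    """
    thresholds = [t for _, t in event_thresholds]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("event thresholds must be strictly increasing")
    d = forecast.trajectory
    events = []
    for name, threshold in event_thresholds:
        idx = np.searchsorted(d, threshold, side="left")
        if idx >= len(d):
            events.append((name, threshold, NOT_REACHED))
        else:
            events.append((name, threshold, forecast.timestamps[idx].date()))
    return PhenologyForecast(
        species_label=forecast.species_label,
        timestamps=forecast.timestamps,
        trajectory=forecast.trajectory,
        start_fraction=forecast.start_fraction,
        events=tuple(events),
    )


def forecast_events(
    model: RateModel,
    series: TemperatureSeries,
    start_fraction: float | None = None,
    event_thresholds: Sequence[tuple[str, float]] | None = None,
) -> PhenologyForecast:
    """Convenience: accumulate development and extract the model's events."""
    fc = accumulate_development(model, series, start_fraction)
    return predict_event_dates(
        fc, event_thresholds if event_thresholds is not None else model.events
    )


def simulate_individuals(
    model: RateModel,
    series: TemperatureSeries,
    n: int = 50,
    sd: float = 0.015,
    seed: int | None = None,
    start_fraction: float | None = None,
    event_thresholds: Sequence[tuple[str, float]] | None = None,
) -> CohortResult:
    """Individual-based cohort simulation with stochastic development rates.

    Each of ``n`` individuals draws its per-timestep rate from
    ``Normal(rate(T_j), sd)`` truncated at 0 (a negative instantaneous
    rate is meaningless) and accumulates independently.  Timesteps where
    the deterministic rate is zero (outside the thermal window) contribute
    exactly zero for every individual: the threshold clamp dominates the
    stochasticity, otherwise truncation would manufacture development
    during winter.  With ``sd = 0`` every individual reproduces the
    deterministic forecast exactly.  The headline "first date" of an event
    is the earliest individual crossing.
    """
    if n < 1:
        raise ValueError("need at least one individual")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    _check_window(series)
    if start_fraction is None:
        start_fraction = model.start_fraction
    if event_thresholds is None:
        event_thresholds = model.events

    base_rates = np.asarray(evaluate_rate(model, series.temperatures))
    rng = np.random.default_rng(seed)
    event_dates: dict[str, list] = {name: [] for name, _ in event_thresholds}
    for _ in range(n):
        if sd == 0.0:
            rates = base_rates
        else:
            rates = np.maximum(rng.normal(base_rates, sd), 0.0)
            rates[base_rates == 0.0] = 0.0
        increments = rates * series.step_days
        trajectory = start_fraction + np.concatenate(([0.0], np.cumsum(increments[1:])))
        for name, threshold in event_thresholds:
            idx = np.searchsorted(trajectory, threshold, side="left")
            event_dates[name].append(
                NOT_REACHED if idx >= len(trajectory) else series.timestamps[idx].date()
            )
    return CohortResult(
        species_label=model.species_label,
        event_dates=event_dates,
        n=n,
        sd=sd,
        seed=seed,
    )


def stage_fraction_from_ratio(
    stage_ratio: Sequence[tuple[str, float]],
    completed: Sequence[str],
) -> float:
    """Fraction of total development completed after a prefix of stages.

    ``stage_ratio`` is an ordered list of (stage name, relative duration);
    ``completed`` must name a prefix of those stages.  E.g. with stage
    durations in ratio egg:larva:pupa = 1:4:5, a full-grown larva
    (egg + larva completed) is at (1+4)/(1+4+5) = 0.5 of egg-to-adult
    development.
    """
    names = [s for s, _ in stage_ratio]
    parts = [p for _, p in stage_ratio]
    if any(p <= 0 for p in parts):
        raise ValueError("ratio parts must be positive")
    completed = list(completed)
    unknown = set(completed) - set(names)
    if unknown:
        raise ValueError(f"unknown stage name(s): {sorted(unknown)}")
    if names[: len(completed)] != completed:
        raise ValueError(
            "completed stages must be a prefix of the stage list "
            f"(expected prefix of {names}, got {completed})"
        )
    return sum(parts[: len(completed)]) / sum(parts)


# ---------------------------------------------------------------------------
# I/O

def read_temperature_series(
    path: str | Path, resolution: str | None = None
) -> TemperatureSeries:
    """Read a weather file: delimited text with ``timestamp`` (ISO-8601)
    and ``temperature_c`` columns; resolution auto-detected unless given."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"timestamp", "temperature_c"} - set(df.columns)
    if missing:
        raise SeriesError(f"weather file missing columns: {sorted(missing)}")
    return TemperatureSeries.from_frame(df, resolution=resolution)


def write_event_report(forecast: PhenologyForecast, path: str | Path) -> None:
    """Write an event table (event, threshold, date) as CSV; dates ISO-8601."""
    rows = [
        {
            "species": forecast.species_label,
            "event": name,
            "threshold": threshold,
            "date": d.isoformat() if isinstance(d, date) else d,
        }
        for name, threshold, d in forecast.events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
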