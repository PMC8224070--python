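"""Observed-vs-predicted validation of phenology forecasts.

Dates are compared as integer day indices counted from a 31 March origin
(1 April -> 1).  Observed first-detection dates derived from trap-check
brackets are the midpoint of the last negative and first positive check,
half days rounded toward the earlier day (conservative for spray
warnings).  Accuracy is quantified by ordinary least squares of observed
on predicted day indices — an ideal forecast gives the line y = x with
r = 1 — together with MAE, RMSE and mean signed error in days.

Two small field-trial formula utilities (parasitism degree per 10 cm2 of
colony surface, and two-sided leaf wall area) live here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValidationTable",
    "AccuracyReport",
    "StatisticsError",
    "date_to_day_index",
    "day_index_to_date",
    "mean_observation_date",
    "regress_observed_on_predicted",
    "error_metrics",
    "parasitism_degree",
    "compute_lwa",
    "read_observations",
    "write_accuracy_report",
]

logger = logging.getLogger(__name__)

DAY_INDEX_ORIGIN = (3, 31)  # 31 March


class StatisticsError(ValueError):
    """Raised when a validation statistic cannot be computed."""


@dataclass(frozen=True)
class ValidationRow:
    year: int
    predicted: date | None
    observed: date | None
    last_negative: date | None = None
    first_positive: date | None = None

    @property
    def complete(self) -> bool:
        return self.predicted is not None and self.observed is not None


@dataclass(frozen=True)
class ValidationTable:
    """Per-year predicted vs observed dates for one phenological event."""

    event: str
    rows: tuple[ValidationRow, ...]

    def complete_rows(self) -> list[ValidationRow]:
        dropped = sum(1 for r in self.rows if not r.complete)
        if dropped:
            logger.info(
                "%s: dropping %d incomplete row(s) of %d", self.event, dropped, len(self.rows)
            )
        return [r for r in self.rows if r.complete]

    @classmethod
    def from_pairs(
        cls, event: str, pairs: Sequence[tuple[int, date | None, date | None]]
    ) -> "ValidationTable":
        return cls(
            event=event,
            rows=tuple(ValidationRow(year=y, predicted=p, observed=o) for y, p, o in pairs),
        )


@dataclass(frozen=True)
class AccuracyReport:
    """Regression and error summary of a validation table."""

    event: str
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    mean_absolute_error: float
    rmse: float
    mean_signed_error: float


def date_to_day_index(d: date, origin_month_day: tuple[int, int] = DAY_INDEX_ORIGIN) -> int:
    """Days after the origin (default 31 March) in the date's own year.

    1 April -> 1, 6 May -> 36.  Dates on or before the origin are
    rejected: the monitoring season starts in April.
    """
    origin = date(d.year, *origin_month_day)
    idx = (d - origin).days
    if idx <= 0:
        raise ValueError(f"{d.isoformat()} is on or before the {origin.isoformat()} origin")
    return idx


def day_index_to_date(
    idx: int, year: int, origin_month_day: tuple[int, int] = DAY_INDEX_ORIGIN
) -> date:
    """Inverse of :func:`date_to_day_index` for a given year."""
    if idx <= 0:
        raise ValueError("day index must be >= 1")
    return date(year, *origin_month_day) + timedelta(days=idx)


def mean_observation_date(
    last_negative: date, first_positive: date, max_interval_days: int = 14
) -> date:
    """Midpoint of a trap-check bracket, half days rounded to the earlier day.

    ``last_negative`` is the last check with no detection and
    ``first_positive`` the first check with one; the true event lies in
    between, so its best single-date estimate is the midpoint.  Intervals
    longer than ``max_interval_days`` are rejected as a sanity guard.
    """
    span = (first_positive - last_negative).days
    if span <= 0:
        raise ValueError(
            f"first positive check {first_positive} must fall after the last "
            f"negative check {last_negative}"
        )
    if span > max_interval_days:
        raise ValueError(f"bracket of {span} days exceeds the {max_interval_days}-day guard")
    return last_negative + timedelta(days=span // 2)


def regress_observed_on_predicted(table: ValidationTable) -> AccuracyReport:
    """OLS of observed (y) on predicted (x) day indices.

    r_squared is the squared Pearson correlation; the p-value is the
    two-sided t-test of slope != 0 with n - 2 degrees of freedom.
    Incomplete rows are dropped (logged); at least 3 complete rows are
    required.
    """
    rows = table.complete_rows()
    if len(rows) < 3:
        raise StatisticsError(
            f"regression needs >= 3 complete rows, {table.event!r} has {len(rows)}"
        )
    x = np.array([date_to_day_index(r.predicted) for r in rows], float)
    y = np.array([date_to_day_index(r.observed) for r in rows], float)
    lr = stats.linregress(x, y)
    mae, rmse, signed = error_metrics(table)
    return AccuracyReport(
        event=table.event,
        n=len(rows),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r_squared=float(lr.rvalue**2),
        p_value=float(lr.pvalue),
        mean_absolute_error=mae,
        rmse=rmse,
        mean_signed_error=signed,
    )


def error_metrics(table: ValidationTable) -> tuple[float, float, float]:
    """(MAE, RMSE, mean signed error) of observed - predicted, in days.

    All three are reported because a bare "mean error of +/- k days" does
    not pin down which statistic is meant.
    """
    rows = table.complete_rows()
    if not rows:
        raise StatisticsError(f"no complete rows in {table.event!r}")
    diffs = np.array([(r.observed - r.predicted).days for r in rows], float)
    mae = float(np.mean(np.abs(diffs)))
    rmse = float(np.sqrt(np.mean(diffs**2)))
    signed = float(np.mean(diffs))
    return mae, rmse, signed


def parasitism_degree(mummy_count: float, colony_surface_cm2: float) -> float:
    """Parasitized aphids per 10 cm2 of woolly-aphid colony surface."""
    if colony_surface_cm2 <= 0:
        raise ValueError("colony surface must be positive")
    if mummy_count < 0:
        raise ValueError("mummy count must be >= 0")
    return 10.0 * mummy_count / colony_surface_cm2


def compute_lwa(n_trees: float, row_spacing_m: float, treated_height_m: float) -> float:
    """Two-sided leaf wall area (m2): trees x in-row spacing x height x 2."""
    if n_trees <= 0 or row_spacing_m <= 0 or treated_height_m <= 0:
        raise ValueError("all LWA inputs must be positive")
    return n_trees * row_spacing_m * treated_height_m * 2.0


# ---------------------------------------------------------------------------
# I/O

def _parse_date(value) -> date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "NA", "nan"):
        return None
    return date.fromisoformat(s)


def read_observations(path: str | Path, event: str | None = None) -> list[ValidationTable]:
    """Read a validation table from delimited text.

    Columns: ``year``, ``event``, ``predicted`` (optional) and either
    ``observed`` or the bracket pair ``last_negative``/``first_positive``
    (ISO dates; blank or NA for missing).  When brackets are given without
    an explicit observed date, the midpoint convention is applied.
    Returns one table per distinct event (filtered to ``event`` if given).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "year" not in df.columns or "event" not in df.columns:
        raise ValueError("observation file needs 'year' and 'event' columns")
    tables = []
    for ev, group in df.groupby("event", sort=False):
        if event is not None and ev != event:
            continue
        rows = []
        for _, rec in group.iterrows():
            last_neg = _parse_date(rec.get("last_negative"))
            first_pos = _parse_date(rec.get("first_positive"))
            observed = _parse_date(rec.get("observed"))
            if observed is None and last_neg is not None and first_pos is not None:
                observed = mean_observation_date(last_neg, first_pos)
            rows.append(
                ValidationRow(
                    year=int(rec["year"]),
                    predicted=_parse_date(rec.get("predicted")),
                    observed=observed,
                    last_negative=last_neg,
                    first_positive=first_pos,
                )
            )
        tables.append(ValidationTable(event=str(ev), rows=tuple(rows)))
    return tables


def write_accuracy_report(reports: Sequence[AccuracyReport], path: str | Path) -> None:
    """Write accuracy reports as CSV (one row per event)."""
    pd.DataFrame([vars(r) for r in reports]).to_csv(path, index=False)


def format_accuracy_report(report: AccuracyReport) -> str:
    """Human-readable one-event accuracy summary."""
    return (
        f"{report.event} (n={report.n})\n"
        f"  regression observed ~ predicted: y = {report.slope:.4f} x "
        f"+ {report.intercept:.4f}\n"
        f"  R-squared = {report.r_squared:.4f}, p-value = {report.p_value:.4g}\n"
        f"  MAE = {report.mean_absolute_error:.2f} d, "
        f"RMSE = {report.rmse:.2f} d, "
        f"mean signed error = {report.mean_signed_error:+.2f} d"
    )
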