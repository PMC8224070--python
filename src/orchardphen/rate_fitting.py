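"""Fit rate curves to development-time-at-constant-temperature data.

Observed development times ``t_i`` at constant temperatures ``T_i`` are
converted to rates ``1/t_i`` and a polynomial rate curve is fitted by
nonlinear least squares (Levenberg-Marquardt via
:func:`scipy.optimize.least_squares`), with starting values from an
ordinary linear polynomial solve.  Because rates, not times, are fitted,
short development times (warm temperatures) dominate the loss.

Candidate fits are compared by AIC under a Gaussian error likelihood,
``AIC = n * ln(RSS / n) + 2k`` with ``k = (number of coefficients) + 1``
for the error variance; additive constants are dropped since only AIC
differences matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .rate_models import RateModel, make_polynomial_model

__all__ = [
    "DevDataset",
    "FitResult",
    "FittingError",
    "fit_rate_model",
    "compare_models",
    "residual_diagnostics",
    "read_dev_dataset",
    "aic_gaussian",
]

# RSS below this is treated as an exact interpolation; the Gaussian AIC
# would be -inf, so a floor is applied and a warning issued instead.
_RSS_FLOOR = 1e-30


class FittingError(RuntimeError):
    """Raised when a rate-model fit cannot be computed."""


@dataclass(frozen=True)
class DevDataset:
    """(temperature degC, development time days) observations for one species.

    Records may carry an optional life-stage label; temperatures must be
    distinct within each stage and development times strictly positive.
    """

    records: tuple[tuple[float, float, str], ...]
    species_label: str = ""

    def __post_init__(self) -> None:
        for temp, dev_time, _stage in self.records:
            if not np.isfinite(temp):
                raise ValueError("temperature must be finite")
            if not dev_time > 0:
                raise ValueError(f"development time must be > 0, got {dev_time}")
        for stage in {r[2] for r in self.records}:
            temps = [r[0] for r in self.records if r[2] == stage]
            if len(temps) != len(set(temps)):
                raise ValueError(
                    f"duplicate temperatures within stage {stage!r}"
                )

    @classmethod
    def from_pairs(
        cls,
        pairs: Sequence[tuple[float, float]],
        species_label: str = "",
        stage: str = "total",
    ) -> "DevDataset":
        return cls(
            records=tuple((float(t), float(d), stage) for t, d in pairs),
            species_label=species_label,
        )

    def subset(self, stage: str) -> "DevDataset":
        return DevDataset(
            records=tuple(r for r in self.records if r[2] == stage),
            species_label=self.species_label,
        )

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([r[0] for r in self.records])

    @property
    def dev_times(self) -> np.ndarray:
        return np.array([r[1] for r in self.records])

    @property
    def rates(self) -> np.ndarray:
        return 1.0 / self.dev_times

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear least-squares rate-model fit."""

    model: RateModel
    residual_sum_of_squares: float
    aic: float
    n_obs: int
    residuals: tuple[float, ...]
    dataset: DevDataset = field(compare=False)
    exact_interpolation: bool = False

    @property
    def n_params(self) -> int:
        return len(self.model.coefficients) + 1  # + error variance


def aic_gaussian(rss: float, n: int, k: int) -> float:
    """Gaussian-likelihood AIC, constants dropped: n*ln(RSS/n) + 2k."""
    rss = max(rss, _RSS_FLOOR)
    return n * np.log(rss / n) + 2 * k


def fit_rate_model(
    data: DevDataset,
    family: str = "polynomial",
    degree: int = 5,
    lower_threshold: float = 0.0,
    seed: int | None = None,
    *,
    stage: str | None = None,
    species_label: str | None = None,
) -> FitResult:
    """Fit a polynomial rate model to ``data`` by nonlinear least squares.

    Starting values come from a deterministic linear least-squares
    polynomial solve on (T, 1/t) pairs, so the result is deterministic
    given the data; ``seed`` is accepted for interface symmetry but not
    needed by the optimizer.

    Raises
    ------
    FittingError
        If the system is underdetermined (fewer than ``degree + 1``
        records) or the optimizer fails to converge.
    """
    if family != "polynomial":
        raise FittingError(f"only the polynomial family is fitted, got {family!r}")
    if stage is not None:
        data = data.subset(stage)
    n = len(data)
    n_coef = degree + 1
    if n < n_coef:
        raise FittingError(
            f"need at least {n_coef} records to fit degree {degree}, got {n}"
        )

    temps = data.temperatures
    rates = data.rates

    # deterministic warm start: ordinary polynomial LS on (T, 1/t)
    x0 = np.polynomial.polynomial.polyfit(temps, rates, degree)

    def resid(coef: np.ndarray) -> np.ndarray:
        return rates - np.polynomial.polynomial.polyval(temps, coef)

    sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15)
    if not sol.success:
        raise FittingError(f"nonlinear least squares did not converge: {sol.message}")

    residuals = resid(sol.x)
    rss = float(np.dot(residuals, residuals))
    exact = rss < _RSS_FLOOR or n == n_coef and rss < 1e-20
    if rss < _RSS_FLOOR:
        warnings.warn(
            "residual sum of squares underflows (exact interpolation); "
            "AIC floored instead of -inf",
            RuntimeWarning,
            stacklevel=2,
        )

    model = make_polynomial_model(
        coefficients=sol.x,
        lower_threshold=lower_threshold,
        species_label=species_label
        or data.species_label
        or f"fitted degree-{degree} polynomial",
    )
    return FitResult(
        model=model,
        residual_sum_of_squares=rss,
        aic=aic_gaussian(rss, n, n_coef + 1),
        n_obs=n,
        residuals=tuple(residuals),
        dataset=data,
        exact_interpolation=exact,
    )


def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits of the *same* dataset by ascending AIC.

    Returns a DataFrame with one row per fit: label, degree, n_obs, RSS,
    AIC and delta-AIC relative to the best model.

    Raises
    ------
    ValueError
        If the fits are not all on the same dataset.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0].dataset
    for f in fits[1:]:
        if f.dataset.records != ref.records:
            raise ValueError("fits being compared come from different datasets")
    rows = [
        {
            "label": f.model.species_label,
            "degree": len(f.model.coefficients) - 1,
            "n_obs": f.n_obs,
            "rss": f.residual_sum_of_squares,
            "aic": f.aic,
            "exact_interpolation": f.exact_interpolation,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table


def residual_diagnostics(fit: FitResult) -> dict:
    """Residual table plus summary statistics for a fit.

    Returns a dict with a per-record DataFrame (temperature, observed
    rate, fitted rate, residual) and summary scalars ``max_abs_residual``
    and ``sign_runs`` (number of runs of same-signed residuals, a crude
    lack-of-fit indicator).
    """
    temps = fit.dataset.temperatures
    observed = fit.dataset.rates
    residuals = np.asarray(fit.residuals)
    fitted = observed - residuals
    table = pd.DataFrame(
        {
            "temperature_c": temps,
            "observed_rate": observed,
            "fitted_rate": fitted,
            "residual": residuals,
        }
    )
    signs = np.sign(residuals[np.abs(residuals) > 0])
    sign_runs = 0 if signs.size == 0 else 1 + int(np.sum(signs[1:] != signs[:-1]))
    return {
        "table": table,
        "max_abs_residual": float(np.max(np.abs(residuals))) if len(residuals) else 0.0,
        "sign_runs": sign_runs,
    }


def read_dev_dataset(path: str | Path, species_label: str = "") -> DevDataset:
    """Read a development-time dataset from delimited text.

    Requires a header with ``temperature_c`` and ``dev_time_days``
    columns; an optional ``stage`` column labels life stages (defaults to
    ``"total"``).  The delimiter is sniffed by pandas.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"temperature_c", "dev_time_days"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dataset is missing columns: {sorted(missing)}")
    stages = df["stage"] if "stage" in df.columns else ["total"] * len(df)
    records = tuple(
        (float(t), float(d), str(s))
        for t, d, s in zip(df["temperature_c"], df["dev_time_days"], stages)
    )
    return DevDataset(records=records, species_label=species_label)
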