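from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orchardphen.phenology_engine import (
    NOT_REACHED,
    SeriesError,
    TemperatureSeries,
    accumulate_development,
    forecast_events,
    predict_event_dates,
    read_temperature_series,
    simulate_individuals,
    stage_fraction_from_ratio,
)
from orchardphen.rate_models import make_linear_dd_model
from orchardphen.synthetic_data import ClimateParams, generate_temperature_series

from .conftest import constant_series


class TestAccumulation:
    def test_closed_form_dd_crossing(self, amali_dd, warm_series):
        # constant 18.3 degC: rate = 10/254.8 per day, head start 0.5
        # => remaining 0.5 generations after 12.74 days, first crossing day 13
        fc = accumulate_development(amali_dd, warm_series, start_fraction=0.5)
        rate = 10.0 / 254.8
        assert fc.trajectory[0] == 0.5
        assert fc.trajectory[13] == pytest.approx(0.5 + 13 * rate, rel=1e-12)
        crossing = np.searchsorted(fc.trajectory, 1.0)
        assert crossing == 13  # ceil(12.74)

    def test_cold_series_stays_flat(self, elanigerum_dd, cold_series):
        fc = accumulate_development(elanigerum_dd, cold_series, start_fraction=0.2)
        assert np.all(fc.trajectory == 0.2)

    def test_trajectory_monotone(self, amali_poly):
        series = generate_temperature_series(ClimateParams(year=2018), seed=3)
        fc = accumulate_development(amali_poly, series)
        assert np.all(np.diff(fc.trajectory) >= 0)

    def test_starts_at_start_fraction(self, amali_poly, warm_series):
        fc = accumulate_development(amali_poly, warm_series, start_fraction=0.5)
        assert fc.trajectory[0] == 0.5

    def test_zero_contribution_outside_window(self, amali_poly):
        # alternate warm/cold days: cold steps must change D by exactly 0
        idx = pd.date_range("2018-01-01", periods=100, freq="D")
        temps = np.where(np.arange(100) % 2 == 0, 20.0, 4.0)
        series = TemperatureSeries(idx, temps.astype(float), "daily")
        fc = accumulate_development(amali_poly, series)
        deltas = np.diff(fc.trajectory)
        cold_steps = temps[1:] <= amali_poly.lower_threshold
        assert np.all(deltas[cold_steps] == 0.0)
        assert np.all(deltas[~cold_steps] > 0.0)

    def test_hourly_vs_daily_resolution_consistency(self, amali_poly):
        # smooth noise-free climate without a diurnal cycle (a nonlinear
        # rate curve legitimately responds to diurnal swings around the
        # threshold): event dates at the two resolutions agree to < 1 day
        hourly = generate_temperature_series(
            ClimateParams(
                innovation_sd_c=0.0, diurnal_amplitude_c=0.0,
                resolution="hourly", year=2018,
            ),
            seed=0,
        )
        daily_means = (
            pd.Series(hourly.temperatures, index=hourly.timestamps)
            .resample("D")
            .mean()
        )
        daily = TemperatureSeries(
            daily_means.index, daily_means.to_numpy(), "daily"
        )
        ev_h = dict(
            (n, d) for n, _t, d in forecast_events(amali_poly, hourly).events
        )
        ev_d = dict(
            (n, d) for n, _t, d in forecast_events(amali_poly, daily).events
        )
        for name in ev_h:
            assert abs((ev_h[name] - ev_d[name]).days) <= 1

    def test_series_must_start_by_jan1(self, amali_dd):
        idx = pd.date_range("2018-02-01", periods=100, freq="D")
        series = TemperatureSeries(idx, np.full(100, 15.0), "daily")
        with pytest.raises(SeriesError):
            accumulate_development(amali_dd, series)


class TestEventExtraction:
    def test_g1_first_crossing(self, amali_dd, warm_series):
        fc = forecast_events(amali_dd, warm_series)
        events = dict((n, d) for n, _t, d in fc.events)
        assert events["G1 adults"] == date(2018, 1, 14)  # index 13

    def test_g2_one_generation_after_g1(self, amali_dd, warm_series):
        fc = forecast_events(amali_dd, warm_series)
        events = dict((n, d) for n, _t, d in fc.events)
        # one full generation at 18.3 degC = 25.48 days; first crossings
        # at ceil(12.74)=13 and ceil(38.22)=39 days
        assert (events["G2 adults"] - events["G1 adults"]).days == 39 - 13

    def test_not_reached_is_valid(self, amali_dd, cold_series):
        fc = forecast_events(amali_dd, cold_series)
        assert all(d == NOT_REACHED for _n, _t, d in fc.events)

    def test_thresholds_must_increase(self, amali_dd, warm_series):
        fc = accumulate_development(amali_dd, warm_series)
        with pytest.raises(ValueError):
            predict_event_dates(fc, [("a", 2.0), ("b", 1.0)])

    def test_event_date_never_precedes_crossing(self, elanigerum_poly):
        series = generate_temperature_series(ClimateParams(year=2019), seed=11)
        fc = forecast_events(elanigerum_poly, series)
        for _name, threshold, d in fc.events:
            if d == NOT_REACHED:
                continue
            below = fc.trajectory < threshold
            last_below = fc.timestamps[below][-1]
            assert d >= last_below.date()


class TestCohort:
    def test_sd_zero_equals_deterministic(self, amali_poly, warm_series):
        fc = forecast_events(amali_poly, warm_series)
        cohort = simulate_individuals(
            amali_poly, warm_series, n=5, sd=0.0, seed=1
        )
        det = dict((n, d) for n, _t, d in fc.events)
        for name, dates in cohort.event_dates.items():
            assert all(d == det[name] for d in dates)

    def test_cohort_first_not_after_deterministic(self, amali_poly):
        series = generate_temperature_series(
            ClimateParams(innovation_sd_c=0.5, year=2018), seed=5
        )
        fc = forecast_events(amali_poly, series)
        det = dict((n, d) for n, _t, d in fc.events)
        cohort = simulate_individuals(amali_poly, series, n=50, sd=0.015, seed=5)
        s = cohort.summary("G1 adults")
        assert s["first"] <= det["G1 adults"]
        assert abs((s["median"] - det["G1 adults"]).days) <= 2

    def test_reproducible_per_seed(self, amali_poly, warm_series):
        c1 = simulate_individuals(amali_poly, warm_series, n=10, sd=0.015, seed=9)
        c2 = simulate_individuals(amali_poly, warm_series, n=10, sd=0.015, seed=9)
        assert c1.event_dates == c2.event_dates

    def test_larger_cohort_earlier_first_date(self, amali_dd):
        # extreme-value monotonicity: E[min of 2n] <= E[min of n]
        series = constant_series(14.0, days=200)
        firsts = {25: [], 50: []}
        for rep in range(60):
            for n in (25, 50):
                c = simulate_individuals(
                    amali_dd, series, n=n, sd=0.015, seed=1000 * n + rep
                )
                s = c.summary("G1 adults")
                firsts[n].append(s["first"].toordinal())
        assert np.mean(firsts[50]) <= np.mean(firsts[25])

    def test_zero_individuals_rejected(self, amali_dd, warm_series):
        with pytest.raises(ValueError):
            simulate_individuals(amali_dd, warm_series, n=0)


class TestStageFraction:
    RATIO = [("egg", 1.0), ("larva", 4.0), ("pupa", 5.0)]

    def test_full_grown_larva_is_half(self):
        assert stage_fraction_from_ratio(self.RATIO, ["egg", "larva"]) == 0.5

    def test_nothing_completed(self):
        assert stage_fraction_from_ratio(self.RATIO, []) == 0.0

    def test_egg_only(self):
        assert stage_fraction_from_ratio(self.RATIO, ["egg"]) == pytest.approx(0.1)

    def test_unknown_stage(self):
        with pytest.raises(ValueError):
            stage_fraction_from_ratio(self.RATIO, ["imago"])

    def test_non_prefix_rejected(self):
        with pytest.raises(ValueError):
            stage_fraction_from_ratio(self.RATIO, ["larva"])


class TestSeriesValidation:
    def test_gap_fill_small(self):
        idx = pd.date_range("2018-01-01", periods=50, freq="D")
        keep = np.ones(50, bool)
        keep[20] = False  # a single missing day: within the fill window
        df = pd.DataFrame(
            {"timestamp": idx[keep], "temperature_c": np.full(keep.sum(), 12.0)}
        )
        series = TemperatureSeries.from_frame(df, resolution="daily")
        assert len(series) == 50

    def test_gap_too_large(self):
        idx = pd.date_range("2018-01-01", periods=50, freq="D")
        keep = np.ones(50, bool)
        keep[20:25] = False
        df = pd.DataFrame(
            {"timestamp": idx[keep], "temperature_c": np.full(keep.sum(), 12.0)}
        )
        with pytest.raises(SeriesError, match="gap"):
            TemperatureSeries.from_frame(df, resolution="daily")

    def test_out_of_range_temperature(self):
        idx = pd.date_range("2018-01-01", periods=10, freq="D")
        with pytest.raises(SeriesError):
            TemperatureSeries(idx, np.full(10, 60.0), "daily")

    def test_reader_autodetects_resolution(self, tmp_path):
        idx = pd.date_range("2018-01-01", periods=48, freq="h")
        path = tmp_path / "weather.csv"
        pd.DataFrame(
            {"timestamp": idx.astype(str), "temperature_c": 10.0}
        ).to_csv(path, index=False)
        series = read_temperature_series(path)
        assert series.resolution == "hourly"
        assert series.step_days == pytest.approx(1 / 24)


@given(
    temps=st.lists(
        st.floats(min_value=-10, max_value=35, allow_nan=False),
        min_size=10,
        max_size=60,
    ),
    start=st.floats(min_value=0, max_value=0.9),
)
@settings(max_examples=100, deadline=None)
def test_property_trajectory_monotone_any_series(temps, start):
    idx = pd.date_range("2018-01-01", periods=len(temps), freq="D")
    series = TemperatureSeries(idx, np.array(temps), "daily")
    model = make_linear_dd_model(8.3, 254.8)
    fc = accumulate_development(model, series, start_fraction=start)
    assert fc.trajectory[0] == start
    assert np.all(np.diff(fc.trajectory) >= 0)
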