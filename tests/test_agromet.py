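import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropclock import (
    ArgumentError,
    CoverageError,
    DateWindow,
    DegreeDayRule,
    MissingDataError,
    WindowSpec,
    daily_degree_day,
    day_of_financial_year,
    growing_degree_days,
    resolve_window,
    stress_days,
    window_stat,
)
from cropclock.weather_io import SyntheticWeatherParams, simulate_weather

from conftest import make_constant_series


@pytest.mark.parametrize(
    "tmin,tmax,expected",
    [
        (15, 35, 17.5),   # cap applied before averaging: (30+15)/2 - 5
        (2, 4, 0.0),      # negative truncated to zero
        (5, 5, 0.0),      # boundary equals base
        (15, 25, 15.0),
    ],
)
def test_daily_degree_day(tmin, tmax, expected):
    assert daily_degree_day(tmin, tmax, DegreeDayRule(5, 30)) == pytest.approx(expected)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    tmin=st.floats(-10, 35),
    diurnal=st.floats(0, 20),
    extra=st.floats(0, 15),
)
def test_daily_degree_day_properties(tmin, diurnal, extra):
    """Non-negative, monotone in tmax, and invariant above the cap."""
    rule = DegreeDayRule()
    tmax = tmin + diurnal
    value = daily_degree_day(tmin, tmax, rule)
    assert value >= 0
    assert daily_degree_day(tmin, tmax + extra, rule) >= value - 1e-12
    if tmax >= rule.t_cap:
        assert daily_degree_day(tmin, tmax + extra, rule) == value


def test_daily_degree_day_rejects_inverted_temps():
    with pytest.raises(ArgumentError):
        daily_degree_day(20, 10)


def test_degree_day_rule_requires_base_below_cap():
    with pytest.raises(ArgumentError):
        DegreeDayRule(t_base=30, t_cap=30)


def test_gdd_constant_weather():
    series = make_constant_series(tmin=15, tmax=25)
    window = DateWindow(dt.date(2021, 2, 1), dt.date(2021, 2, 3))
    assert growing_degree_days(series, window) == pytest.approx(45.0)


def test_gdd_single_day_equals_daily():
    series = make_constant_series(tmin=12, tmax=28)
    window = DateWindow(dt.date(2021, 3, 1), dt.date(2021, 3, 1))
    assert growing_degree_days(series, window) == pytest.approx(daily_degree_day(12, 28))


def test_gdd_outside_coverage_names_missing_dates():
    series = make_constant_series(n_days=30)
    with pytest.raises(CoverageError) as err:
        growing_degree_days(series, DateWindow(dt.date(2021, 1, 20), dt.date(2021, 2, 20)))
    assert err.value.missing_dates


@pytest.fixture(scope="module")
def noisy_series():
    return simulate_weather(
        SyntheticWeatherParams(seed=3, noise_sd=3.0), dt.date(2018, 7, 1), 800,
        location_id="noisy",
    )


def _random_windows(series, rng, n=200, max_len=60):
    start0 = series.start.toordinal()
    end0 = series.end.toordinal()
    for _ in range(n):
        a = rng.integers(start0, end0 - max_len)
        length = rng.integers(1, max_len)
        yield DateWindow(dt.date.fromordinal(int(a)), dt.date.fromordinal(int(a + length)))


def test_gdd_matches_bruteforce_oracle(noisy_series):
    """Windowed thermal time equals an independent day-by-day loop."""
    rng = np.random.default_rng(0)
    rule = DegreeDayRule()
    for window in _random_windows(noisy_series, rng, n=200):
        expected = 0.0
        day = window.start
        while day <= window.end:
            row = noisy_series.frame.loc[str(day)]
            expected += max(
                0.0, (min(float(row["tmax"]), rule.t_cap) + float(row["tmin"])) / 2 - rule.t_base
            )
            day += dt.timedelta(days=1)
        assert growing_degree_days(noisy_series, window, rule) == pytest.approx(
            expected, abs=1e-9
        )


def test_gdd_additivity(noisy_series):
    """GDD over [a,b] + [b+1,c] equals GDD over [a,c] at machine precision."""
    rng = np.random.default_rng(1)
    for window in _random_windows(noisy_series, rng, n=50, max_len=40):
        if window.n_days < 2:
            continue
        mid = window.start + dt.timedelta(days=window.n_days // 2)
        left = growing_degree_days(noisy_series, DateWindow(window.start, mid))
        right = growing_degree_days(
            noisy_series, DateWindow(mid + dt.timedelta(days=1), window.end)
        )
        total = growing_degree_days(noisy_series, window)
        assert left + right == pytest.approx(total, abs=1e-9)


def test_gdd_monotonic_in_window_and_base(noisy_series):
    w_short = DateWindow(dt.date(2018, 9, 1), dt.date(2018, 9, 20))
    w_long = DateWindow(dt.date(2018, 9, 1), dt.date(2018, 10, 20))
    assert growing_degree_days(noisy_series, w_short) <= growing_degree_days(
        noisy_series, w_long
    )
    low_base = growing_degree_days(noisy_series, w_long, DegreeDayRule(3, 30))
    high_base = growing_degree_days(noisy_series, w_long, DegreeDayRule(8, 30))
    assert high_base <= low_base


def test_cap_invariance():
    """Raising tmax above the cap leaves the daily value unchanged."""
    rule = DegreeDayRule(5, 30)
    base_val = daily_degree_day(18, 30, rule)
    for tmax in (31, 35, 45):
        assert daily_degree_day(18, tmax, rule) == base_val


def test_stress_days_strict_threshold():
    series = make_constant_series(n_days=3, tmax=26)
    series.frame.loc[:, "tmax"] = [26.0, 28.0, 31.0]
    window = DateWindow(dt.date(2021, 1, 1), dt.date(2021, 1, 3))
    assert stress_days(series, window, 27.5) == 2
    assert stress_days(series, window, 30.0) == 1
    assert stress_days(series, window, -100.0) == 3  # saturation: window length


def test_stress_days_monotone_in_threshold(noisy_series):
    window = DateWindow(dt.date(2019, 1, 1), dt.date(2019, 2, 28))
    counts = [stress_days(noisy_series, window, t) for t in (20, 25, 27.5, 30, 35)]
    assert counts == sorted(counts, reverse=True)


def test_window_stat_examples():
    series = make_constant_series(n_days=3, radiation=10)
    series.frame.loc[:, "radiation"] = [10.0, 20.0, 30.0]
    window = DateWindow(dt.date(2021, 1, 1), dt.date(2021, 1, 3))
    assert window_stat(series, window, "radiation", "sum") == pytest.approx(60)
    assert window_stat(series, window, "radiation", "mean") == pytest.approx(20)
    assert window_stat(series, window, "tmean", "mean") == pytest.approx(20)


def test_window_stat_oracle(noisy_series):
    rng = np.random.default_rng(2)
    for window in _random_windows(noisy_series, rng, n=40):
        sub = noisy_series.frame.loc[str(window.start): str(window.end)]
        assert window_stat(noisy_series, window, "tmax", "mean") == pytest.approx(
            float(sub["tmax"].mean())
        )
        assert window_stat(noisy_series, window, "radiation", "sum") == pytest.approx(
            float(sub["radiation"].sum())
        )


def test_window_stat_missing_variable_errors():
    series = make_constant_series()
    series.frame.drop(columns=["vp"], inplace=True)
    window = DateWindow(dt.date(2021, 2, 1), dt.date(2021, 2, 5))
    with pytest.raises(MissingDataError):
        window_stat(series, window, "vapour_pressure", "mean")


@pytest.mark.parametrize(
    "date,expected",
    [
        (dt.date(2021, 7, 1), 1),
        (dt.date(2020, 7, 1), 1),
        (dt.date(2021, 6, 30), 365),
        (dt.date(2021, 2, 19), 234),
    ],
)
def test_day_of_financial_year(date, expected):
    assert day_of_financial_year(date) == expected


def test_resolve_vegetative_window_length():
    window = resolve_window(
        dt.date(2021, 2, 19), dt.date(2021, 4, 1), None,
        WindowSpec("sowing", end_anchor="petal_fall"),
    )
    assert window.n_days == 41
    assert window.end == dt.date(2021, 4, 1)
    assert window.start == dt.date(2021, 2, 20)


def test_resolve_fixed_after():
    window = resolve_window(
        dt.date(2021, 2, 19), None, None, WindowSpec("sowing", n_days=7)
    )
    assert window.start == dt.date(2021, 2, 20)
    assert window.end == dt.date(2021, 2, 26)


def test_resolve_fixed_before():
    window = resolve_window(
        None, dt.date(2021, 4, 1), None,
        WindowSpec("petal_fall", n_days=5, direction="before"),
    )
    assert window.start == dt.date(2021, 3, 27)
    assert window.end == dt.date(2021, 3, 31)


def test_resolve_window_ordering_error():
    with pytest.raises(ArgumentError):
        resolve_window(
            dt.date(2021, 4, 1), dt.date(2021, 2, 19), None,
            WindowSpec("sowing", end_anchor="petal_fall"),
        )


def test_resolve_window_missing_anchor_error():
    with pytest.raises(ArgumentError, match="petal_fall"):
        resolve_window(
            dt.date(2021, 2, 19), None, None,
            WindowSpec("sowing", end_anchor="petal_fall"),
        )


def test_window_spec_validation():
    with pytest.raises(ArgumentError):
        WindowSpec("sowing")  # neither end_anchor nor n_days
    with pytest.raises(ArgumentError):
        WindowSpec("sowing", n_days=0)
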