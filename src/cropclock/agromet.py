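"""Derived agro-meteorological variables over phenology-anchored windows.

Thermal time (growing degree days) uses the capped-average convention: the
daily maximum is capped at ``t_cap`` *before* averaging with the minimum,
the base is subtracted, and negative daily values truncate to zero.  The
minimum is not floored at the base.  Defaults are a 5 °C base and a 30 °C
cap, the convention for field-grown beans on daily temperatures.

Windows are anchored on crop phenology dates (sowing, petal fall, harvest).
A window from one anchor to another excludes the start-anchor day and
includes the end-anchor day, so its length in days equals the plain date
difference — e.g. sowing 19 Feb to petal fall 1 Apr is a 41-day vegetative
window.  Fixed-length windows after an anchor start the day after it;
windows before an anchor end the day before it.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ArgumentError, MissingDataError
from .weather_io import WeatherSeries

__all__ = [
    "DegreeDayRule",
    "WindowSpec",
    "DateWindow",
    "daily_degree_day",
    "growing_degree_days",
    "stress_days",
    "window_stat",
    "day_of_financial_year",
    "resolve_window",
]

Anchor = Literal["sowing", "petal_fall", "harvest"]


@dataclass(frozen=True)
class DegreeDayRule:
    """Base/cap truncation rule for daily degree days (°C)."""

    t_base: float = 5.0
    t_cap: float = 30.0

    def __post_init__(self):
        if not self.t_base < self.t_cap:
            raise ArgumentError(
                f"t_base ({self.t_base}) must be below t_cap ({self.t_cap})"
            )


@dataclass(frozen=True)
class DateWindow:
    """An inclusive calendar-date interval."""

    start: dt.date
    end: dt.date

    def __post_init__(self):
        if self.start > self.end:
            raise ArgumentError(f"window start {self.start} after end {self.end}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass(frozen=True)
class WindowSpec:
    """Declarative description of a phenology-anchored window.

    Either ``end_anchor`` (anchor-to-anchor window) or ``n_days`` (fixed
    length, ``direction`` 'after' or 'before' the anchor) must be given.
    """

    anchor: Anchor
    end_anchor: Anchor | None = None
    n_days: int | None = None
    direction: Literal["after", "before"] = "after"

    def __post_init__(self):
        if (self.end_anchor is None) == (self.n_days is None):
            raise ArgumentError("specify exactly one of end_anchor or n_days")
        if self.n_days is not None and self.n_days < 1:
            raise ArgumentError("fixed window length must be >= 1 day")


def daily_degree_day(tmin: float, tmax: float, rule: DegreeDayRule = DegreeDayRule()) -> float:
    """Degree days for one day: max(0, (min(tmax, cap) + tmin)/2 − base)."""
    if tmin > tmax:
        raise ArgumentError(f"tmin ({tmin}) exceeds tmax ({tmax})")
    return max(0.0, (min(tmax, rule.t_cap) + tmin) / 2.0 - rule.t_base)


def growing_degree_days(
    series: WeatherSeries, window: DateWindow, rule: DegreeDayRule = DegreeDayRule()
) -> float:
    """Thermal time: sum of daily degree days over the window (°C d)."""
    sub = series.slice_window(window.start, window.end)
    capped = np.minimum(sub["tmax"].to_numpy(), rule.t_cap)
    daily = (capped + sub["tmin"].to_numpy()) / 2.0 - rule.t_base
    return float(np.sum(np.maximum(daily, 0.0)))


def stress_days(series: WeatherSeries, window: DateWindow, threshold: float) -> int:
    """Number of window days whose maximum temperature strictly exceeds ``threshold``."""
    sub = series.slice_window(window.start, window.end)
    return int((sub["tmax"].to_numpy() > threshold).sum())


_VARIABLE_COLUMNS = {
    "tmin": "tmin",
    "tmax": "tmax",
    "radiation": "radiation",
    "vapour_pressure": "vp",
    "rain": "rain",
}
_STATS = {"mean": np.mean, "sum": np.sum, "min": np.min, "max": np.max}


def window_stat(
    series: WeatherSeries,
    window: DateWindow,
    variable: str,
    statistic: Literal["mean", "sum", "min", "max"] = "mean",
) -> float:
    """Apply a statistic to one weather variable over a window.

    ``tmean`` is the per-day average of tmin and tmax.  Raises
    :class:`MissingDataError` if the variable is absent for any window day.
    """
    if statistic not in _STATS:
        raise ArgumentError(f"unknown statistic {statistic!r}")
    sub = series.slice_window(window.start, window.end)
    if variable == "tmean":
        values = (sub["tmin"].to_numpy() + sub["tmax"].to_numpy()) / 2.0
    else:
        col = _VARIABLE_COLUMNS.get(variable)
        if col is None:
            raise ArgumentError(f"unknown variable {variable!r}")
        if col not in sub.columns:
            raise MissingDataError(
                f"variable {variable!r} not recorded for {series.location_id!r}"
            )
        values = sub[col].to_numpy(dtype=float)
        if np.isnan(values).any():
            bad = sub.index[np.isnan(values)].date.tolist()
            raise MissingDataError(
                f"variable {variable!r} missing on {bad[:5]} in window "
                f"{window.start}..{window.end}"
            )
    return float(_STATS[statistic](values))


def day_of_financial_year(d: dt.date) -> int:
    """Ordinal day within the Australian financial year: 1 July = day 1."""
    fy_start_year = d.year if d.month >= 7 else d.year - 1
    return (d - dt.date(fy_start_year, 7, 1)).days + 1


def resolve_window(
    sowing: dt.date | None,
    petal_fall: dt.date | None,
    harvest: dt.date | None,
    spec: WindowSpec,
) -> DateWindow:
    """Turn a :class:`WindowSpec` into concrete dates for one crop record.

    Anchor-to-anchor windows span ``[start_anchor + 1 d, end_anchor]``;
    fixed windows span ``[anchor + 1, anchor + n]`` (after) or
    ``[anchor − n, anchor − 1]`` (before).
    """
    anchors = {"sowing": sowing, "petal_fall": petal_fall, "harvest": harvest}
    start_anchor = anchors[spec.anchor]
    if start_anchor is None:
        raise ArgumentError(f"required anchor {spec.anchor!r} is absent")
    one = dt.timedelta(days=1)
    if spec.end_anchor is not None:
        end_anchor = anchors[spec.end_anchor]
        if end_anchor is None:
            raise ArgumentError(f"required anchor {spec.end_anchor!r} is absent")
        if end_anchor <= start_anchor:
            raise ArgumentError(
                f"{spec.end_anchor} ({end_anchor}) not after {spec.anchor} "
                f"({start_anchor})"
            )
        return DateWindow(start_anchor + one, end_anchor)
    n = dt.timedelta(days=spec.n_days)
    if spec.direction == "after":
        return DateWindow(start_anchor + one, start_anchor + n)
    return DateWindow(start_anchor - n, start_anchor - one)
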