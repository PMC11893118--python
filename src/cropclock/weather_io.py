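"""Daily weather series: SILO-like CSV I/O and synthetic Queensland-style weather.

The on-disk dialect is a plain daily CSV with one row per calendar day and
columns ``date, tmin, tmax, radiation`` plus optional ``rain`` and ``vp``
(vapour pressure, hPa).  Real SILO "patched point" exports use different
column headers and compact ``YYYYMMDD`` dates; both are accepted, either via
built-in aliases or an explicit dialect map.

The synthetic generator produces a southern-hemisphere sinusoidal annual
cycle (summer peak in mid-January by default) with independent Gaussian
daily noise — enough seasonal structure to exercise every derived
agro-meteorological variable offline.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, CoverageError, FormatError, ValidationError

__all__ = [
    "DailyWeatherRecord",
    "WeatherSeries",
    "SyntheticWeatherParams",
    "read_weather_csv",
    "write_weather_csv",
    "simulate_weather",
]

#: canonical column order for the on-disk dialect
CANONICAL_COLUMNS = ("date", "tmin", "tmax", "radiation", "rain", "vp")
MANDATORY_COLUMNS = ("date", "tmin", "tmax", "radiation")

# Lower-cased aliases seen in SILO patched-point exports and common hand-made
# files; an explicit dialect map always wins over these.
_COLUMN_ALIASES: dict[str, str] = {
    "date": "date",
    "date2": "date",
    "day": "date",
    "tmin": "tmin",
    "t.min": "tmin",
    "min_temp": "tmin",
    "mint": "tmin",
    "tmax": "tmax",
    "t.max": "tmax",
    "max_temp": "tmax",
    "maxt": "tmax",
    "radiation": "radiation",
    "radn": "radiation",
    "solar_radiation": "radiation",
    "rain": "rain",
    "rainfall": "rain",
    "daily_rain": "rain",
    "vp": "vp",
    "vapour_pressure": "vp",
    "vprp": "vp",
}

_ISO_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_SILO_RE = re.compile(r"^\d{8}$")


@dataclass(frozen=True)
class DailyWeatherRecord:
    """One location-day of weather observations.

    Temperatures in °C, radiation in MJ m⁻² day⁻¹, rain in mm, vapour
    pressure in hPa.  ``rain`` and ``vapour_pressure`` are optional.
    """

    date: dt.date
    tmin: float
    tmax: float
    radiation: float
    rain: float | None = None
    vapour_pressure: float | None = None

    def __post_init__(self):
        if self.tmin > self.tmax:
            raise ValidationError(
                f"{self.date}: tmin ({self.tmin}) exceeds tmax ({self.tmax})"
            )
        if self.radiation < 0:
            raise ValidationError(f"{self.date}: negative radiation {self.radiation}")
        if self.rain is not None and self.rain < 0:
            raise ValidationError(f"{self.date}: negative rain {self.rain}")
        if self.vapour_pressure is not None and self.vapour_pressure <= 0:
            raise ValidationError(
                f"{self.date}: non-positive vapour pressure {self.vapour_pressure}"
            )


class WeatherSeries:
    """A validated, gap-free daily weather series for one location.

    Internally a :class:`pandas.DataFrame` indexed by consecutive daily
    dates with columns ``tmin, tmax, radiation`` and, when populated,
    ``rain`` and ``vp``.
    """

    def __init__(self, location_id: str, frame: pd.DataFrame):
        self.location_id = str(location_id)
        self.frame = self._validate(frame)

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(
        cls, location_id: str, records: Iterable[DailyWeatherRecord]
    ) -> "WeatherSeries":
        records = list(records)
        frame = pd.DataFrame(
            {
                "tmin": [r.tmin for r in records],
                "tmax": [r.tmax for r in records],
                "radiation": [r.radiation for r in records],
            },
            index=pd.DatetimeIndex([pd.Timestamp(r.date) for r in records]),
        )
        if any(r.rain is not None for r in records):
            frame["rain"] = [np.nan if r.rain is None else r.rain for r in records]
        if any(r.vapour_pressure is not None for r in records):
            frame["vp"] = [
                np.nan if r.vapour_pressure is None else r.vapour_pressure
                for r in records
            ]
        return cls(location_id, frame)

    @staticmethod
    def _validate(frame: pd.DataFrame) -> pd.DataFrame:
        frame = frame.copy()
        frame.index = pd.DatetimeIndex(frame.index).normalize()
        frame.index.name = "date"
        for col in ("tmin", "tmax", "radiation"):
            if col not in frame.columns:
                raise ValidationError(f"weather frame missing column {col!r}")
            if frame[col].isna().any():
                bad = frame.index[frame[col].isna()].date.tolist()
                raise ValidationError(f"missing {col} values on {bad[:5]}")
        if len(frame):
            dup = frame.index[frame.index.duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate dates: {dup.date.tolist()[:5]}")
            if not frame.index.is_monotonic_increasing:
                raise ValidationError("dates are not in increasing order")
            expected = pd.date_range(frame.index[0], frame.index[-1], freq="D")
            if len(expected) != len(frame):
                missing = expected.difference(frame.index).date.tolist()
                raise ValidationError(
                    f"date gaps: missing {missing[:5]}"
                    + ("..." if len(missing) > 5 else "")
                )
            bad = frame.index[frame["tmin"] > frame["tmax"]]
            if len(bad):
                raise ValidationError(
                    f"tmin > tmax on dates: {bad.date.tolist()[:10]}"
                )
            if (frame["radiation"] < 0).any():
                raise ValidationError("negative radiation values present")
            if "rain" in frame.columns and (frame["rain"].dropna() < 0).any():
                raise ValidationError("negative rain values present")
            if "vp" in frame.columns and (frame["vp"].dropna() <= 0).any():
                raise ValidationError("non-positive vapour pressure values present")
        return frame

    # -- access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def start(self) -> dt.date:
        return self.frame.index[0].date()

    @property
    def end(self) -> dt.date:
        return self.frame.index[-1].date()

    @property
    def records(self) -> list[DailyWeatherRecord]:
        has_rain = "rain" in self.frame.columns
        has_vp = "vp" in self.frame.columns
        out = []
        for ts, row in self.frame.iterrows():
            out.append(
                DailyWeatherRecord(
                    date=ts.date(),
                    tmin=float(row["tmin"]),
                    tmax=float(row["tmax"]),
                    radiation=float(row["radiation"]),
                    rain=float(row["rain"]) if has_rain and pd.notna(row["rain"]) else None,
                    vapour_pressure=float(row["vp"])
                    if has_vp and pd.notna(row["vp"])
                    else None,
                )
            )
        return out

    def slice_window(self, start: dt.date, end: dt.date) -> pd.DataFrame:
        """Return the sub-frame for ``[start, end]`` inclusive.

        Raises :class:`CoverageError` naming the missing dates when the
        window is not fully covered.
        """
        start_ts, end_ts = pd.Timestamp(start), pd.Timestamp(end)
        if len(self.frame) == 0 or start_ts < self.frame.index[0] or end_ts > self.frame.index[-1]:
            wanted = pd.date_range(start_ts, end_ts, freq="D")
            missing = wanted.difference(self.frame.index).date.tolist()
            raise CoverageError(
                f"window {start}..{end} not covered by weather for "
                f"{self.location_id!r}; missing {missing[:5]}"
                + ("..." if len(missing) > 5 else ""),
                missing_dates=missing,
            )
        return self.frame.loc[start_ts:end_ts]

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeatherSeries):
            return NotImplemented
        if self.location_id != other.location_id:
            return False
        try:
            pd.testing.assert_frame_equal(
                self.frame, other.frame, check_like=True, check_exact=True,
                check_freq=False,
            )
        except AssertionError:
            return False
        return True


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def _detect_date_format(values: Sequence[str]) -> str:
    """Detect ISO vs compact-SILO date dialect; mixed dialects are rejected."""
    iso = sum(bool(_ISO_RE.match(v)) for v in values)
    silo = sum(bool(_SILO_RE.match(v)) for v in values)
    if iso and silo:
        raise FormatError("mixed date dialects (ISO and YYYYMMDD) within one file")
    if iso == len(values):
        return "%Y-%m-%d"
    if silo == len(values):
        return "%Y%m%d"
    bad_idx = next(
        i for i, v in enumerate(values) if not (_ISO_RE.match(v) or _SILO_RE.match(v))
    )
    raise FormatError(
        f"unparsable date {values[bad_idx]!r} at data line {bad_idx + 2}"
    )


def read_weather_csv(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    location_id: str | None = None,
) -> WeatherSeries:
    """Read a daily weather CSV into a validated :class:`WeatherSeries`.

    Parameters
    ----------
    path
        CSV file with a header row.  Mandatory columns (after dialect
        resolution): date, tmin, tmax, radiation.  Optional: rain, vp.
    dialect
        Map from canonical column name to the column name used in the file,
        e.g. ``{"tmax": "T.Max"}``.  Columns not covered by the map are
        matched against built-in SILO-style aliases; unknown extra columns
        (quality codes, evaporation, ...) are ignored.
    location_id
        Defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"weather file not found: {path}")
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [str(c).strip() for c in raw.columns]

    rename: dict[str, str] = {}
    explicit = {canon: name for canon, name in (dialect or {}).items()}
    for col in raw.columns:
        for canon, name in explicit.items():
            if col == name:
                rename[col] = canon
                break
        else:
            alias = _COLUMN_ALIASES.get(col.lower())
            if alias and alias not in rename.values():
                rename[col] = alias
    table = raw.rename(columns=rename)

    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path.name}")

    if len(table) == 0:
        return WeatherSeries(
            location_id or path.stem,
            pd.DataFrame(columns=["tmin", "tmax", "radiation"],
                         index=pd.DatetimeIndex([], name="date")),
        )

    date_strings = table["date"].astype(str).str.strip().tolist()
    fmt = _detect_date_format(date_strings)
    try:
        dates = pd.to_datetime(date_strings, format=fmt)
    except ValueError as exc:  # format matched but an invalid calendar date
        for i, v in enumerate(date_strings):
            try:
                dt.datetime.strptime(v, fmt)
            except ValueError:
                raise FormatError(
                    f"unparsable date {v!r} at data line {i + 2}"
                ) from exc
        raise

    def parse_float(value) -> float:
        # python float() is correctly rounded, so repr-written values
        # round-trip exactly (pandas' own parser can be off by 1 ulp)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return np.nan
        text = str(value).strip()
        if not text:
            return np.nan
        try:
            return float(text)
        except ValueError:
            return np.nan

    frame = pd.DataFrame(index=pd.DatetimeIndex(dates))
    for col in ("tmin", "tmax", "radiation", "rain", "vp"):
        if col in table.columns:
            frame[col] = np.array([parse_float(v) for v in table[col]])
    for col in ("rain", "vp"):
        if col in frame.columns and frame[col].isna().all():
            frame = frame.drop(columns=[col])
    return WeatherSeries(location_id or path.stem, frame)


def write_weather_csv(series: WeatherSeries, path: str | Path) -> Path:
    """Write a series in the canonical dialect (ISO dates); lossless.

    Numeric fields are written at full ``repr`` precision so that
    ``read_weather_csv(write_weather_csv(s))`` reproduces ``s`` exactly.
    """
    path = Path(path)
    out = series.frame.copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    cols = [c for c in CANONICAL_COLUMNS if c in out.columns]
    try:
        # repr of the python float is the shortest exactly-round-tripping form
        out[cols].to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    except OSError as exc:
        raise FormatError(f"cannot write weather CSV to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Synthetic weather
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticWeatherParams:
    """Parameters of the sinusoidal synthetic weather generator.

    Defaults emulate a South-East Queensland (Lockyer-Valley-like) site:
    warm subtropical summers peaking mid-January (southern hemisphere),
    mild winters, radiation in phase with temperature.  Optional vapour
    pressure and rainfall channels are generated so the full derived
    variable catalogue can be exercised.
    """

    mean_tmax: float = 26.5          # °C, annual mean of daily maximum
    annual_amplitude: float = 5.5    # °C, half-range of the seasonal cycle
    tmin_offset: float = 10.5        # °C, mean diurnal range
    noise_sd: float = 2.5            # °C, sd of independent daily noise
    mean_radiation: float = 18.0     # MJ m⁻², annual mean daily total
    radiation_amplitude: float = 7.0  # MJ m⁻²
    peak_day_of_year: int = 15       # mid-January = austral summer peak
    seed: int = 0
    mean_vp: float = 18.0            # hPa; set ≤ 0 to omit vapour pressure
    vp_amplitude: float = 7.0        # hPa
    rain_probability: float = 0.25   # set 0 to omit rainfall
    rain_mean_mm: float = 8.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ArgumentError("noise_sd must be >= 0")
        if self.annual_amplitude < 0 or self.radiation_amplitude < 0:
            raise ArgumentError("amplitudes must be >= 0")
        if not (1 <= self.peak_day_of_year <= 366):
            raise ArgumentError("peak_day_of_year must be in 1..366")


def simulate_weather(
    params: SyntheticWeatherParams,
    start: dt.date,
    n_days: int,
    location_id: str = "synthetic",
) -> WeatherSeries:
    """Generate a seeded synthetic daily weather series.

    tmax follows ``mean + amplitude·cos(2π(doy − peak)/365.25)`` plus
    Normal(0, noise_sd²) noise; tmin is tmax minus the diurnal offset plus
    independent noise, clamped so tmin ≤ tmax; radiation is an analogous
    sinusoid clamped at ≥ 0.1 MJ m⁻².  The same ``(params, start, n_days)``
    always yields the identical series.
    """
    if n_days < 1:
        raise ArgumentError("n_days must be >= 1")
    rng = np.random.default_rng(params.seed)
    index = pd.date_range(pd.Timestamp(start), periods=n_days, freq="D")
    doy = index.dayofyear.to_numpy(dtype=float)
    phase = np.cos(2 * np.pi * (doy - params.peak_day_of_year) / 365.25)

    tmax = params.mean_tmax + params.annual_amplitude * phase
    tmax = tmax + rng.normal(0.0, params.noise_sd, n_days)
    tmin = tmax - params.tmin_offset + rng.normal(0.0, params.noise_sd, n_days)
    tmin = np.minimum(tmin, tmax)
    radiation = params.mean_radiation + params.radiation_amplitude * phase
    radiation = radiation + rng.normal(0.0, params.noise_sd, n_days)
    radiation = np.maximum(radiation, 0.1)

    frame = pd.DataFrame(
        {"tmin": tmin, "tmax": tmax, "radiation": radiation}, index=index
    )
    if params.rain_probability > 0:
        wet = rng.random(n_days) < params.rain_probability
        amounts = rng.exponential(params.rain_mean_mm, n_days)
        frame["rain"] = np.where(wet, amounts, 0.0)
    if params.mean_vp > 0:
        vp = params.mean_vp + params.vp_amplitude * phase
        vp = vp + rng.normal(0.0, params.noise_sd, n_days)
        frame["vp"] = np.maximum(vp, 0.5)
    return WeatherSeries(location_id, frame)
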