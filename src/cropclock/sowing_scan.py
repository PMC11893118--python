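"""Multi-year sowing-date scans and percentile summaries.

A scan lays a grid of hypothetical sowing dates (every ``step_days`` days
across a date range, per location), assigns each a vegetative and pod-fill
duration — season-specific fixed durations by default, or predictions from
fitted duration models — and derives the full agro-meteorological feature
table for the implied windows.  Group-wise medians with 20th and 80th
percentiles then summarise what a sowing at a given time of year has
historically experienced (thermal time, stress days, radiation, ...).

Quantiles use linear interpolation between closest ranks (the numpy
default, R type 7); the convention is stated because published percentile
tables cannot adjudicate it.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .duration_models import FittedLinearModel, predict_with_interval
from .errors import ArgumentError, ScanError
from .phenology import CropRecord, FeatureDef, build_feature_table
from .weather_io import WeatherSeries

__all__ = ["ScanSpec", "scan_sowings", "percentile_summary"]

logger = logging.getLogger(__name__)

#: fallback fixed durations (days) when a season has no explicit entry;
#: values chosen near the observed medians of the three seasons
DEFAULT_DURATIONS: dict[str, tuple[int, int]] = {
    "Autumn": (41, 21),
    "Spring": (41, 21),
    "Middle": (41, 21),
}


@dataclass(frozen=True)
class ScanSpec:
    """Grid definition for a hypothetical-sowing scan.

    ``fixed_durations`` maps season → (vegetative days, pod-fill days);
    alternatively ``duration_models`` supplies fitted linear models for the
    vegetative and pod-fill durations, applied to features computed from
    provisional fixed-duration windows (two-pass scheme).
    """

    locations: tuple[str, ...]
    start: dt.date
    end: dt.date
    step_days: int = 1
    region_by_location: Mapping[str, str] | None = None  # default SEQ
    fixed_durations: Mapping[str, tuple[int, int]] | None = None
    duration_models: Mapping[str, FittedLinearModel] | None = None  # keys veg/pod

    def __post_init__(self):
        if self.step_days < 1:
            raise ArgumentError("step_days must be >= 1")
        if self.start > self.end:
            raise ArgumentError("scan date range is empty")
        if not self.locations:
            raise ArgumentError("at least one location required")
        for season, (veg, pod) in (self.fixed_durations or {}).items():
            if veg < 1 or pod < 1:
                raise ArgumentError(f"fixed durations for {season!r} must be > 0")


def _hypothetical_records(spec: ScanSpec, durations_by_season) -> list[CropRecord]:
    records = []
    regions = spec.region_by_location or {}
    date = spec.start
    dates = []
    while date <= spec.end:
        dates.append(date)
        date += dt.timedelta(days=spec.step_days)
    for loc in spec.locations:
        region = regions.get(loc, "SEQ")
        for sow in dates:
            # provisional record to classify the season
            season = "Middle" if region == "NEQ" else (
                "Autumn" if sow.month <= 7 else "Spring"
            )
            veg, pod = durations_by_season.get(season, DEFAULT_DURATIONS[season])
            pf = sow + dt.timedelta(days=int(veg))
            hv = pf + dt.timedelta(days=int(pod))
            records.append(
                CropRecord(
                    record_id=f"{loc}:{sow.isoformat()}",
                    location_id=loc,
                    region=region,  # type: ignore[arg-type]
                    sowing=sow,
                    petal_fall=pf,
                    harvest=hv,
                )
            )
    return records


def scan_sowings(
    spec: ScanSpec,
    weather: Mapping[str, WeatherSeries],
    features: Sequence[FeatureDef] | None = None,
) -> pd.DataFrame:
    """Feature table over the hypothetical sowing grid.

    Rows whose growth windows run past the weather coverage are dropped
    (the count is logged).  Raises :class:`ScanError` when nothing remains.
    """
    durations_by_season = dict(spec.fixed_durations or DEFAULT_DURATIONS)
    records = _hypothetical_records(spec, durations_by_season)
    kept = [
        r
        for r in records
        if r.location_id in weather
        and weather[r.location_id].start <= r.sowing
        and r.harvest <= weather[r.location_id].end
    ]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info("scan: dropped %d sowings outside weather coverage", n_dropped)
    if not kept:
        raise ScanError("no hypothetical sowing has full weather coverage")
    table = build_feature_table(kept, weather, features)

    if spec.duration_models:
        # second pass: replace fixed durations with model predictions
        refined: list[CropRecord] = []
        preds: dict[str, tuple[int, int]] = {}
        veg_m = spec.duration_models.get("veg")
        pod_m = spec.duration_models.get("pod")
        for _, row in table.iterrows():
            veg, pod = durations_by_season.get(
                row["season"], DEFAULT_DURATIONS[row["season"]]
            )
            frame = row.to_frame().T
            if veg_m is not None:
                veg = int(round(float(
                    predict_with_interval(veg_m, frame)["prediction"].iloc[0]
                )))
            if pod_m is not None:
                pod = int(round(float(
                    predict_with_interval(pod_m, frame)["prediction"].iloc[0]
                )))
            preds[row["record_id"]] = (max(veg, 1), max(pod, 1))
        for rec in kept:
            veg, pod = preds[rec.record_id]
            pf = rec.sowing + dt.timedelta(days=veg)
            hv = pf + dt.timedelta(days=pod)
            if weather[rec.location_id].end.toordinal() < hv.toordinal():
                continue
            refined.append(
                CropRecord(rec.record_id, rec.location_id, rec.region, rec.sowing, pf, hv)
            )
        if not refined:
            raise ScanError("no sowing remains after model-based duration refinement")
        table = build_feature_table(refined, weather, features)
    return table


def percentile_summary(
    rows: pd.DataFrame,
    group_by: Sequence[str],
    variables: Sequence[str],
    probs: Sequence[float] = (0.2, 0.5, 0.8),
) -> pd.DataFrame:
    """Group-wise order-statistic quantiles (linear interpolation).

    Returns a tidy frame with the group keys, ``variable``, ``n`` and one
    ``p<percent>`` column per requested probability (``p50`` also exposed
    as ``median``).  Row order of the input is irrelevant.
    """
    unknown = [v for v in variables if v not in rows.columns]
    if unknown:
        raise ArgumentError(f"unknown variables: {unknown}")
    missing_keys = [k for k in group_by if k not in rows.columns]
    if missing_keys:
        raise ArgumentError(f"unknown grouping keys: {missing_keys}")
    probs = sorted(probs)
    out = []
    for keys, sub in rows.groupby(list(group_by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for var in variables:
            values = sub[var].dropna().to_numpy(dtype=float)
            if len(values) == 0:
                continue
            q = np.quantile(values, probs, method="linear")
            row = dict(zip(group_by, keys))
            row["variable"] = var
            row["n"] = len(values)
            for prob, val in zip(probs, q):
                row[f"p{int(round(prob * 100))}"] = float(val)
            out.append(row)
    result = pd.DataFrame(out)
    if "p50" in result.columns:
        result["median"] = result["p50"]
    return result
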