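"""Crop records, growth durations, season classification and the feature table.

A :class:`CropRecord` is one commercial sowing with its phenology dates
(sowing, petal fall, harvest) and marketable fresh yield.  The feature
table concords each record with the daily weather for its location and
computes the catalogue of derived agro-meteorological variables — thermal
time, stress-day counts, window means of temperature / radiation / vapour
pressure — for the vegetative (sowing → petal fall), pod-fill (petal fall
→ harvest) and total growth windows plus short fixed post-anchor windows.

Season labels: South-East Queensland sowings split into Autumn (Jan–Jul by
default) and Spring (Aug–Dec); North-East Queensland (Bowen) is the single
'Middle' season.  The month map is configurable because the two published
descriptions of the sowing calendar differ slightly.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .agromet import (
    DateWindow,
    DegreeDayRule,
    WindowSpec,
    day_of_financial_year,
    growing_degree_days,
    resolve_window,
    stress_days,
    window_stat,
)
from .errors import (
    ArgumentError,
    ConcordanceError,
    CoverageError,
    FormatError,
    MissingDataError,
)
from .weather_io import WeatherSeries

__all__ = [
    "CropRecord",
    "Durations",
    "FeatureDef",
    "load_crop_records",
    "durations",
    "classify_season",
    "default_features",
    "build_feature_table",
    "DEFAULT_SEQ_MONTH_MAP",
]

logger = logging.getLogger(__name__)

Region = Literal["SEQ", "NEQ"]
Season = Literal["Autumn", "Spring", "Middle"]

#: default SEQ sowing-month → season map: Jan–Jul Autumn, Aug–Dec Spring
DEFAULT_SEQ_MONTH_MAP: dict[int, str] = {
    **{m: "Autumn" for m in range(1, 8)},
    **{m: "Spring" for m in range(8, 13)},
}


@dataclass(frozen=True)
class CropRecord:
    """One commercial sowing with phenology dates and marketable yield."""

    record_id: str
    location_id: str
    region: Region
    sowing: dt.date
    petal_fall: dt.date | None = None
    harvest: dt.date | None = None
    fresh_yield: float | None = None  # kg/ha, marketable fresh weight

    def __post_init__(self):
        if self.sowing is None:
            raise ArgumentError(f"{self.record_id}: sowing date is required")
        if self.petal_fall is not None and not self.sowing < self.petal_fall:
            raise ArgumentError(
                f"{self.record_id}: petal fall {self.petal_fall} not after "
                f"sowing {self.sowing}"
            )
        if self.harvest is not None:
            ref = self.petal_fall if self.petal_fall is not None else self.sowing
            if not ref < self.harvest:
                raise ArgumentError(
                    f"{self.record_id}: harvest {self.harvest} not after {ref}"
                )
        if self.fresh_yield is not None and self.fresh_yield < 0:
            raise ArgumentError(f"{self.record_id}: negative fresh yield")


@dataclass(frozen=True)
class Durations:
    """Growth-period lengths in days; None when an endpoint is missing."""

    vegetative: int | None
    pod_fill: int | None
    total: int | None


def durations(record: CropRecord) -> Durations:
    """Plain date-difference durations: veg = petal fall − sowing, etc."""
    veg = (record.petal_fall - record.sowing).days if record.petal_fall else None
    pod = (
        (record.harvest - record.petal_fall).days
        if record.harvest and record.petal_fall
        else None
    )
    total = (record.harvest - record.sowing).days if record.harvest else None
    return Durations(veg, pod, total)


def classify_season(
    record: CropRecord, seq_month_map: Mapping[int, str] | None = None
) -> str:
    """Season label for a sowing: NEQ → Middle, SEQ by sowing month."""
    if record.region == "NEQ":
        return "Middle"
    if record.region == "SEQ":
        month_map = dict(seq_month_map) if seq_month_map else DEFAULT_SEQ_MONTH_MAP
        try:
            return month_map[record.sowing.month]
        except KeyError:
            raise ArgumentError(
                f"month {record.sowing.month} missing from season month map"
            ) from None
    raise ArgumentError(f"unknown region {record.region!r} for {record.record_id}")


# ---------------------------------------------------------------------------
# Crop record CSV
# ---------------------------------------------------------------------------

_CROP_COLUMNS = (
    "record_id",
    "location_id",
    "region",
    "sowing",
    "petal_fall",
    "harvest",
    "fresh_yield",
)


def _parse_date(value: str) -> dt.date | None:
    value = (value or "").strip()
    if not value:
        return None
    return dt.date.fromisoformat(value)


def load_crop_records(path: str | Path) -> tuple[list[CropRecord], list[dict]]:
    """Load crop records from CSV; invalid rows go to a validation report.

    Returns ``(records, report)`` where each report entry is a dict with
    ``row`` (1-based data row number), ``record_id`` and ``reason``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"crop record file not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ("record_id", "location_id", "region", "sowing") if c not in header]
        if missing:
            raise FormatError(f"crop CSV missing columns: {missing}")
        records: list[CropRecord] = []
        report: list[dict] = []
        for i, row in enumerate(reader, start=1):
            rid = (row.get("record_id") or f"row{i}").strip()
            try:
                fy = (row.get("fresh_yield") or "").strip()
                records.append(
                    CropRecord(
                        record_id=rid,
                        location_id=(row.get("location_id") or "").strip(),
                        region=(row.get("region") or "").strip(),  # type: ignore[arg-type]
                        sowing=_parse_date(row.get("sowing")),
                        petal_fall=_parse_date(row.get("petal_fall")),
                        harvest=_parse_date(row.get("harvest")),
                        fresh_yield=float(fy) if fy else None,
                    )
                )
            except (ArgumentError, ValueError, TypeError) as exc:
                reason = str(exc)
                if "not after" in reason:
                    reason = f"date ordering: {reason}"
                report.append({"row": i, "record_id": rid, "reason": reason})
    return records, report


# ---------------------------------------------------------------------------
# Feature catalogue
# ---------------------------------------------------------------------------

#: standard growth-period windows
WINDOW_VEG = WindowSpec("sowing", end_anchor="petal_fall")
WINDOW_POD = WindowSpec("petal_fall", end_anchor="harvest")
WINDOW_TOTAL = WindowSpec("sowing", end_anchor="harvest")


@dataclass(frozen=True)
class FeatureDef:
    """One derived-variable definition: a window plus an operation.

    kind 'degree_days' sums daily degree days under ``rule``; 'stress'
    counts days with tmax above ``threshold``; 'stat' applies ``statistic``
    to ``variable`` (see :func:`cropclock.agromet.window_stat`).
    """

    name: str
    window: WindowSpec
    kind: Literal["degree_days", "stress", "stat"]
    variable: str | None = None
    statistic: str = "mean"
    threshold: float | None = None
    rule: DegreeDayRule = field(default_factory=DegreeDayRule)

    def compute(self, series: WeatherSeries, window: DateWindow) -> float:
        if self.kind == "degree_days":
            return growing_degree_days(series, window, self.rule)
        if self.kind == "stress":
            return float(stress_days(series, window, self.threshold))
        if self.kind == "stat":
            return window_stat(series, window, self.variable, self.statistic)
        raise ArgumentError(f"unknown feature kind {self.kind!r}")


def default_features() -> list[FeatureDef]:
    """The standard candidate-predictor catalogue.

    Mirrors the published variable lists: thermal time, window means of
    temperature / radiation / vapour pressure, cumulative radiation and
    stress-day counts at 27.5 °C and 30 °C over the vegetative, pod-fill
    and total windows, plus first-7/14/28-day post-sowing and 5/15-day
    post-petal-fall windows.
    """
    pf5 = WindowSpec("petal_fall", n_days=5)
    pf15 = WindowSpec("petal_fall", n_days=15)
    sow7 = WindowSpec("sowing", n_days=7)
    sow14 = WindowSpec("sowing", n_days=14)
    sow28 = WindowSpec("sowing", n_days=28)
    feats = [
        FeatureDef("thermal_time_veg", WINDOW_VEG, "degree_days"),
        FeatureDef("thermal_time_pod", WINDOW_POD, "degree_days"),
        FeatureDef("thermal_time_total", WINDOW_TOTAL, "degree_days"),
        FeatureDef("cum_radn_veg", WINDOW_VEG, "stat", "radiation", "sum"),
        FeatureDef("cum_radn_pod", WINDOW_POD, "stat", "radiation", "sum"),
        FeatureDef("mean_radn_veg", WINDOW_VEG, "stat", "radiation", "mean"),
        FeatureDef("mean_radn_pod", WINDOW_POD, "stat", "radiation", "mean"),
        FeatureDef("mean_tmin_veg", WINDOW_VEG, "stat", "tmin", "mean"),
        FeatureDef("mean_tmax_veg", WINDOW_VEG, "stat", "tmax", "mean"),
        FeatureDef("mean_tmean_veg", WINDOW_VEG, "stat", "tmean", "mean"),
        FeatureDef("mean_tmin_pod", WINDOW_POD, "stat", "tmin", "mean"),
        FeatureDef("mean_tmax_pod", WINDOW_POD, "stat", "tmax", "mean"),
        FeatureDef("mean_tmean_pod", WINDOW_POD, "stat", "tmean", "mean"),
        FeatureDef("mean_tmin_total", WINDOW_TOTAL, "stat", "tmin", "mean"),
        FeatureDef("mean_vp_veg", WINDOW_VEG, "stat", "vapour_pressure", "mean"),
        FeatureDef("mean_vp_pod", WINDOW_POD, "stat", "vapour_pressure", "mean"),
        FeatureDef("stress27_veg", WINDOW_VEG, "stress", threshold=27.5),
        FeatureDef("stress30_veg", WINDOW_VEG, "stress", threshold=30.0),
        FeatureDef("stress27_pod", WINDOW_POD, "stress", threshold=27.5),
        FeatureDef("stress30_pod", WINDOW_POD, "stress", threshold=30.0),
        FeatureDef("stress30_pf5", pf5, "stress", threshold=30.0),
        FeatureDef("stress30_pf15", pf15, "stress", threshold=30.0),
        FeatureDef("stress27_pf15", pf15, "stress", threshold=27.5),
        FeatureDef("mean_tmax_28d_post_sow", sow28, "stat", "tmax", "mean"),
        FeatureDef("mean_tmin_28d_post_sow", sow28, "stat", "tmin", "mean"),
        FeatureDef("mean_tmax_14d_post_sow", sow14, "stat", "tmax", "mean"),
        FeatureDef("mean_tmin_14d_post_sow", sow14, "stat", "tmin", "mean"),
        FeatureDef("mean_radn_7d_post_sow", sow7, "stat", "radiation", "mean"),
        FeatureDef("mean_radn_28d_post_sow", sow28, "stat", "radiation", "mean"),
        FeatureDef("mean_vp_28d_post_sow", sow28, "stat", "vapour_pressure", "mean"),
    ]
    return feats


def build_feature_table(
    records: Sequence[CropRecord],
    weather: Mapping[str, WeatherSeries],
    features: Sequence[FeatureDef] | None = None,
    seq_month_map: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """One row of derived variables per crop record.

    Features whose windows cannot be resolved (missing anchor) or covered
    (weather gap) or whose variable is unrecorded are set to NaN with the
    reason logged; they are never silently zero.  Records whose location has
    no weather series raise :class:`ConcordanceError` listing record ids.
    """
    if features is None:
        features = default_features()
    unmatched = [r.record_id for r in records if r.location_id not in weather]
    if unmatched:
        raise ConcordanceError(
            f"no weather series for records: {unmatched[:10]}"
            + ("..." if len(unmatched) > 10 else ""),
            record_ids=unmatched,
        )
    rows = []
    for rec in records:
        series = weather[rec.location_id]
        dur = durations(rec)
        row: dict[str, object] = {
            "record_id": rec.record_id,
            "location_id": rec.location_id,
            "region": rec.region,
            "season": classify_season(rec, seq_month_map),
            "sowing": pd.Timestamp(rec.sowing),
            "sowing_day_fy": day_of_financial_year(rec.sowing),
            "duration_veg": np.nan if dur.vegetative is None else dur.vegetative,
            "duration_pod": np.nan if dur.pod_fill is None else dur.pod_fill,
            "duration_total": np.nan if dur.total is None else dur.total,
            "fresh_yield": np.nan if rec.fresh_yield is None else rec.fresh_yield,
        }
        for feat in features:
            try:
                window = resolve_window(rec.sowing, rec.petal_fall, rec.harvest, feat.window)
                row[feat.name] = feat.compute(series, window)
            except (ArgumentError, CoverageError, MissingDataError) as exc:
                row[feat.name] = np.nan
                logger.info("%s: feature %s missing (%s)", rec.record_id, feat.name, exc)
        rows.append(row)
    return pd.DataFrame(rows)
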