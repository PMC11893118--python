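"""Yield-component estimation, error propagation and sampling-size rules.

Fresh pod yield decomposes multiplicatively:

    fresh weight yield = plants per area × pods per plant × pod weight.

Field samples (counts and pod mass on a fixed quadrat, e.g. 0.5625 m² of
0.75 m row) give a direct per-sample yield estimate; the product of the
three component means gives a second estimator whose standard error is
propagated by the first-order delta method under independence.  The
sample-size rule converts an observed coefficient of variation into the
minimum number of quadrats needed to estimate a mean within a relative
error at a given confidence.

Unit convention, fixed and unit-tested: kg/ha = grams × 10 / area_m².
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ArgumentError

__all__ = [
    "FieldSample",
    "FieldSampleSet",
    "Estimate",
    "ComponentEstimates",
    "per_sample_yield",
    "component_estimates",
    "product_of_means_yield",
    "maturity_proportions",
    "required_sample_size",
    "MATURE_POD_WEIGHT_G",
]

#: mature marketable pod reference weight (g); 4.9 g is the tabulated variant
MATURE_POD_WEIGHT_G = 4.91


@dataclass(frozen=True)
class Estimate:
    """A mean with its standard error."""

    mean: float
    se: float

    def __post_init__(self):
        if self.se < 0:
            raise ArgumentError("standard error must be >= 0")


@dataclass(frozen=True)
class FieldSample:
    """Counts and total pod mass from one sampled quadrat."""

    plants: int
    pods: int
    pod_mass_total: float  # g

    def __post_init__(self):
        if self.plants < 0 or self.pods < 0 or self.pod_mass_total < 0:
            raise ArgumentError("sample counts and mass must be >= 0")


@dataclass(frozen=True)
class FieldSampleSet:
    """Random quadrat samples taken on one date in one field."""

    sample_area: float  # m² per quadrat
    samples: tuple[FieldSample, ...]
    sample_date: dt.date | None = None
    sowing: dt.date | None = None
    petal_fall: dt.date | None = None
    harvest: dt.date | None = None

    def __post_init__(self):
        if self.sample_area <= 0:
            raise ArgumentError("sample_area must be > 0")

    @property
    def n(self) -> int:
        return len(self.samples)


def _mean_se(values: np.ndarray) -> Estimate:
    n = len(values)
    return Estimate(float(np.mean(values)), float(np.std(values, ddof=1) / math.sqrt(n)))


def _g_per_m2_to_kg_per_ha(grams: np.ndarray, area_m2: float) -> np.ndarray:
    # g / m² × 10 000 m²/ha ÷ 1000 g/kg = ×10
    return grams * 10.0 / area_m2


def per_sample_yield(s: FieldSampleSet) -> Estimate:
    """Fresh yield (kg/ha): mean and se of per-quadrat scaled pod mass."""
    if s.n < 2:
        raise ArgumentError("at least 2 samples required for a standard error")
    per = _g_per_m2_to_kg_per_ha(
        np.array([smp.pod_mass_total for smp in s.samples], dtype=float), s.sample_area
    )
    return _mean_se(per)


def component_estimates(s: FieldSampleSet) -> "ComponentEstimates":
    """Component means/ses and both yield estimators from one sample set."""
    if s.n < 2:
        raise ArgumentError("at least 2 samples required for standard errors")
    plants = np.array([smp.plants for smp in s.samples], dtype=float)
    pods = np.array([smp.pods for smp in s.samples], dtype=float)
    mass = np.array([smp.pod_mass_total for smp in s.samples], dtype=float)
    density = _mean_se(plants / s.sample_area * 10_000.0)  # plants/ha
    with np.errstate(divide="ignore", invalid="ignore"):
        pods_per_plant = _mean_se(np.where(plants > 0, pods / plants, np.nan))
        pod_weight = _mean_se(np.where(pods > 0, mass / pods, np.nan))
    direct = per_sample_yield(s)
    return ComponentEstimates(
        plant_density=density,
        pods_per_plant=pods_per_plant,
        pod_weight=pod_weight,
        fresh_yield=direct,
        n_samples=s.n,
    )


@dataclass(frozen=True)
class ComponentEstimates:
    """Per-component estimates and the direct per-sample yield (kg/ha)."""

    plant_density: Estimate   # plants/ha
    pods_per_plant: Estimate
    pod_weight: Estimate      # g
    fresh_yield: Estimate     # kg/ha, per-sample estimator
    n_samples: int


def product_of_means_yield(
    density: Estimate, pods: Estimate, pod_weight: Estimate
) -> Estimate:
    """Yield (kg/ha) as density × pods/plant × pod weight with delta-method se.

    Components are treated as independent, so the relative variance of the
    product is the sum of squared component CVs (first-order delta method).
    Note this product-of-means estimator need not match the per-sample
    estimator on the same data: the latter averages per-quadrat products.
    """
    for e in (density, pods, pod_weight):
        if e.mean <= 0:
            raise ArgumentError("component means must be > 0")
    mean = density.mean * pods.mean * pod_weight.mean / 1000.0  # g/ha → kg/ha
    rel_var = sum((e.se / e.mean) ** 2 for e in (density, pods, pod_weight))
    return Estimate(mean, mean * math.sqrt(rel_var))


def maturity_proportions(
    current_pod_weight: float,
    sampled_yield: float,
    final_yield: float,
    mature_pod_weight: float = MATURE_POD_WEIGHT_G,
) -> tuple[float, float]:
    """Pod-weight and yield maturity proportions, reported to 3 decimals.

    weight proportion = current mean pod weight / mature marketable pod
    weight; yield proportion = sampled yield / final marketable yield.
    """
    if mature_pod_weight <= 0 or final_yield <= 0:
        raise ArgumentError("reference denominators must be > 0")
    return (
        round(current_pod_weight / mature_pod_weight, 3),
        round(sampled_yield / final_yield, 3),
    )


def required_sample_size(
    mean: float,
    se: float,
    n_observed: int,
    rel_error: float = 0.10,
    confidence: float = 0.95,
) -> int:
    """Minimum quadrat count to estimate a mean within ``rel_error``.

    Recovers the per-sample CV from the observed standard error of the mean
    (CV = se·√n / mean) and applies the z-based rule
    n = ⌈(z·CV/rel_error)²⌉, floored at 1.
    """
    if mean <= 0:
        raise ArgumentError("mean must be > 0")
    if se < 0:
        raise ArgumentError("se must be >= 0")
    if n_observed < 2:
        raise ArgumentError("n_observed must be >= 2")
    if not 0 < rel_error < 1 or not 0 < confidence < 1:
        raise ArgumentError("rel_error and confidence must be in (0, 1)")
    cv = se * math.sqrt(n_observed) / mean
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return max(1, math.ceil((z * cv / rel_error) ** 2))
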