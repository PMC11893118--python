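"""Linear models of growth-period durations with stepwise-AIC selection.

Vegetative, pod-fill and total durations (days) are regressed on the
agro-meteorological candidate catalogues.  The workflow is: screen highly
correlated candidate pairs, fit the full ordinary-least-squares model, then
backward stepwise selection dropping at each step the variable whose
removal most lowers the AIC (ties toward the later-listed variable, per the
parsimony principle), stopping when no removal lowers it.  Predictions
carry t-based prediction intervals (80 % coverage by default) that include
both residual and estimation variance.

AIC convention: n·ln(RSS/n) + 2·(p + 1) with p the coefficient count
including the intercept; additive constants dropped, matching the grouped
logistic module so model comparisons use one scale.

OLS fitting and interval construction delegate to statsmodels; the
selection and screening logic, AIC convention and complete-case handling
are defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .errors import ArgumentError
from .growth_models import aic_from_rss

__all__ = [
    "ModelSpec",
    "FittedLinearModel",
    "collinearity_filter",
    "fit_ols",
    "backward_stepwise",
    "predict_with_interval",
    "default_candidate_catalogue",
    "dump_candidate_catalogue",
    "load_candidate_catalogue",
]


@dataclass(frozen=True)
class ModelSpec:
    """Response column, ordered candidate predictors and optional season filter."""

    response: str
    candidates: tuple[str, ...]
    season: str | None = None

    def __post_init__(self):
        if not self.candidates:
            raise ArgumentError("candidate list must be non-empty")
        if self.response in self.candidates:
            raise ArgumentError("response must not appear among candidates")


#: published candidate-predictor catalogues per response × season
_CANDIDATE_CATALOGUE: dict[str, dict] = {
    "vegetative_both_seasons": {
        "response": "duration_veg",
        "season": None,
        "candidates": ["sowing_day_fy", "thermal_time_veg", "mean_radn_veg"],
    },
    "vegetative_autumn": {
        "response": "duration_veg",
        "season": "Autumn",
        "candidates": [
            "sowing_day_fy",
            "thermal_time_veg",
            "mean_tmin_veg",
            "mean_radn_veg",
            "cum_radn_veg",
            "mean_tmax_28d_post_sow",
            "mean_radn_7d_post_sow",
            "mean_radn_28d_post_sow",
            "mean_tmin_28d_post_sow",
            "mean_vp_28d_post_sow",
            "mean_tmax_14d_post_sow",
            "mean_tmin_14d_post_sow",
        ],
    },
    "pod_fill_both_seasons": {
        "response": "duration_pod",
        "season": None,
        "candidates": [
            "thermal_time_pod",
            "stress30_pf5",
            "stress30_pod",
            "mean_tmin_total",
            "stress30_pf15",
            "stress27_pf15",
        ],
    },
    "total_autumn": {
        "response": "duration_total",
        "season": "Autumn",
        "candidates": [
            "sowing_day_fy",
            "cum_radn_veg",
            "mean_radn_veg",
            "stress27_veg",
        ],
    },
    "total_spring": {
        "response": "duration_total",
        "season": "Spring",
        "candidates": [
            "cum_radn_veg",
            "mean_radn_veg",
            "thermal_time_veg",
            "mean_tmax_veg",
            "mean_tmin_veg",
        ],
    },
}


def default_candidate_catalogue() -> dict[str, ModelSpec]:
    """The shipped response × season candidate lists as :class:`ModelSpec`."""
    return {
        name: ModelSpec(
            response=entry["response"],
            candidates=tuple(entry["candidates"]),
            season=entry["season"],
        )
        for name, entry in _CANDIDATE_CATALOGUE.items()
    }


def dump_candidate_catalogue(path: str | Path) -> Path:
    """Write the default catalogue as editable YAML."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(_CANDIDATE_CATALOGUE, fh, sort_keys=False)
    return path


def load_candidate_catalogue(path: str | Path) -> dict[str, ModelSpec]:
    """Load a (possibly edited) catalogue YAML into :class:`ModelSpec` objects."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        name: ModelSpec(
            response=entry["response"],
            candidates=tuple(entry["candidates"]),
            season=entry.get("season"),
        )
        for name, entry in raw.items()
    }


# ---------------------------------------------------------------------------
# Collinearity screen
# ---------------------------------------------------------------------------


def collinearity_filter(
    feature_table: pd.DataFrame,
    candidates: Sequence[str],
    r_max: float = 0.95,
) -> tuple[list[str], list[dict]]:
    """Drop later-listed members of highly correlated candidate pairs.

    Constant (zero-variance) candidates are dropped first with reason
    'constant'.  Remaining pairs are scanned in candidate order; when
    |Pearson r| ≥ ``r_max`` the later-listed variable is dropped.
    Deterministic given the candidate order.  Returns (retained, report).
    """
    data = feature_table[list(candidates)].dropna()
    if len(data) < 2:
        raise ArgumentError("need at least 2 complete rows for the collinearity screen")
    report: list[dict] = []
    active: list[str] = []
    for name in candidates:
        if float(data[name].std(ddof=0)) == 0.0:
            report.append({"dropped": name, "reason": "constant"})
        else:
            active.append(name)
    corr = data[active].corr().abs() if active else pd.DataFrame()
    retained: list[str] = []
    dropped: set[str] = set()
    for i, a in enumerate(active):
        if a in dropped:
            continue
        retained.append(a)
        for b in active[i + 1:]:
            if b in dropped:
                continue
            r = float(corr.loc[a, b])
            if r >= r_max:
                dropped.add(b)
                report.append(
                    {"dropped": b, "reason": f"|r| = {r:.3f} with {a!r}", "kept": a}
                )
    return retained, report


# ---------------------------------------------------------------------------
# OLS with the shared AIC convention
# ---------------------------------------------------------------------------


@dataclass
class FittedLinearModel:
    """An OLS fit with the package AIC convention and its selection trace."""

    response: str
    variables: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    n: int
    rss: float
    sigma2: float
    aic: float
    trace: list[dict] = field(default_factory=list)
    _results: object = None  # statsmodels RegressionResults

    @property
    def n_coefficients(self) -> int:
        return len(self.params)


def _design(feature_table: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    X = feature_table[list(variables)].astype(float) if variables else pd.DataFrame(
        index=feature_table.index
    )
    X.insert(0, "const", 1.0)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    if np.linalg.matrix_rank(arr) == arr.shape[1]:
        return
    aliased, rank = [], 0
    for j in range(arr.shape[1]):
        r = np.linalg.matrix_rank(arr[:, : j + 1])
        if r == rank:
            aliased.append(X.columns[j])
        rank = r
    raise ArgumentError(f"rank-deficient design; aliased columns: {aliased}")


def fit_ols(feature_table: pd.DataFrame, spec: ModelSpec) -> FittedLinearModel:
    """Ordinary least squares on complete cases with the package AIC.

    Rows with any missing response or candidate value are excluded
    (complete-case analysis).  A rank-deficient design raises an error
    naming the aliased columns.  With a perfect fit (RSS = 0) the AIC is
    the −inf sentinel.
    """
    if spec.season is not None and "season" in feature_table.columns:
        feature_table = feature_table[feature_table["season"] == spec.season]
    cols = [spec.response, *spec.candidates]
    data = feature_table[cols].dropna()
    n = len(data)
    p = len(spec.candidates) + 1
    if n < p + 2:
        raise ArgumentError(
            f"only {n} complete cases for {p} coefficients (+2 required)"
        )
    X = _design(data, spec.candidates)
    _check_rank(X)
    results = sm.OLS(data[spec.response].astype(float), X).fit()
    rss = float(results.ssr)
    return FittedLinearModel(
        response=spec.response,
        variables=tuple(spec.candidates),
        params=results.params,
        bse=results.bse,
        n=n,
        rss=rss,
        sigma2=rss / results.df_resid if results.df_resid > 0 else float("nan"),
        aic=aic_from_rss(rss, n, p),
        _results=results,
    )


def backward_stepwise(feature_table: pd.DataFrame, spec: ModelSpec) -> FittedLinearModel:
    """Backward stepwise AIC selection starting from the full candidate set.

    At each step the single variable whose removal most lowers the AIC is
    dropped; ties break toward the later-listed variable; selection stops
    when no removal lowers the AIC.  The fitted model carries the selection
    trace (variable dropped and AIC after each accepted step).
    """
    current = list(spec.candidates)
    # freeze the complete-case rows of the FULL model so every candidate AIC
    # in the search is computed on the same n
    if spec.season is not None and "season" in feature_table.columns:
        feature_table = feature_table[feature_table["season"] == spec.season]
    feature_table = feature_table.dropna(subset=[spec.response, *spec.candidates])
    model = fit_ols(feature_table, ModelSpec(spec.response, tuple(current), spec.season))
    trace = [{"dropped": None, "aic": model.aic, "variables": tuple(current)}]
    while current:
        best_candidate: FittedLinearModel | None = None
        best_var: str | None = None
        # scan in reverse so an exact AIC tie keeps the later-listed drop
        for var in reversed(current):
            reduced = [v for v in current if v != var]
            if reduced:
                cand = fit_ols(
                    feature_table, ModelSpec(spec.response, tuple(reduced), spec.season)
                )
            else:
                cand = _fit_intercept_only(feature_table, spec)
            if best_candidate is None or cand.aic < best_candidate.aic:
                best_candidate, best_var = cand, var
        if best_candidate is not None and best_candidate.aic < model.aic:
            current.remove(best_var)
            model = best_candidate
            trace.append(
                {"dropped": best_var, "aic": model.aic, "variables": tuple(current)}
            )
        else:
            break
    model.trace = trace
    return model


def _fit_intercept_only(feature_table: pd.DataFrame, spec: ModelSpec) -> FittedLinearModel:
    if spec.season is not None and "season" in feature_table.columns:
        feature_table = feature_table[feature_table["season"] == spec.season]
    data = feature_table[[spec.response, *spec.candidates]].dropna()
    y = data[spec.response].astype(float)
    n = len(y)
    X = _design(data, [])
    results = sm.OLS(y, X).fit()
    rss = float(results.ssr)
    return FittedLinearModel(
        response=spec.response,
        variables=(),
        params=results.params,
        bse=results.bse,
        n=n,
        rss=rss,
        sigma2=rss / results.df_resid if results.df_resid > 0 else float("nan"),
        aic=aic_from_rss(rss, n, 1),
        _results=results,
    )


def predict_with_interval(
    model: FittedLinearModel,
    new_rows: pd.DataFrame,
    level: float = 0.80,
) -> pd.DataFrame:
    """Point predictions with symmetric t-based prediction intervals.

    The interval includes both residual variance and coefficient-estimation
    variance (leverage term).  Returns a frame with columns ``prediction``,
    ``lower``, ``upper`` indexed like ``new_rows``.
    """
    if not 0.0 < level < 1.0:
        raise ArgumentError("level must be in (0, 1)")
    missing = [v for v in model.variables if v not in new_rows.columns]
    if missing:
        raise ArgumentError(f"new rows missing model variables: {missing}")
    X = _design(new_rows, model.variables)
    pred = model._results.get_prediction(X)
    frame = pred.summary_frame(alpha=1.0 - level)
    return pd.DataFrame(
        {
            "prediction": frame["mean"].to_numpy(),
            "lower": frame["obs_ci_lower"].to_numpy(),
            "upper": frame["obs_ci_upper"].to_numpy(),
        },
        index=new_rows.index,
    )
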