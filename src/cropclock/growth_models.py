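"""Canopy energy budget, photothermal productivity index, and logistic pod growth.

The pod-growth model is the three-parameter logistic of fresh pod weight
against thermal time after petal fall,

    f(x) = Asym / (1 + exp((xmid − x) / scal)),

fitted by nonlinear least squares with an analytic Jacobian and a
self-starting initialisation (logit regression of the scaled response).
Season-grouped fits compare three nested parameter-sharing structures —
all parameters shared, separate Asym and xmid with a common scal, and all
separate — and select by AIC with a parsimony margin: among structures
whose AIC lies within 2 units of the minimum, the one with the fewest
parameters wins, reflecting the principle that a simpler model is favoured
when fits are statistically indistinguishable.

Thermal times at or above 1080 °C d are excluded before fitting (pods past
that point turn stringy and fresh weight is past its optimum, so those
observations no longer lie on the growth curve).

AIC convention throughout: n·ln(RSS/n) + 2·(p + 1), additive constants
dropped; the same convention is used by the duration models so comparisons
are coherent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ArgumentError, FitError

__all__ = [
    "CanopyEnergyParams",
    "ProductivityInputs",
    "LogisticParams",
    "LogisticFit",
    "GroupedLogisticFit",
    "primary_production",
    "yield_potential",
    "productivity_index",
    "logistic_value",
    "fit_logistic",
    "fit_grouped_logistic",
    "simulate_grouped_logistic",
    "aic_from_rss",
    "DEFAULT_MAX_THERMAL_TIME",
]

#: fresh weight past its optimum (stringy pods) above this thermal time
DEFAULT_MAX_THERMAL_TIME = 1080.0

#: parsimony margin: structures within this many AIC units of the minimum
#: are treated as indistinguishable and the simplest of them is selected
AIC_PARSIMONY_MARGIN = 2.0


def aic_from_rss(rss: float, n: int, n_params: int) -> float:
    """AIC as n·ln(RSS/n) + 2·(p+1).

    A numerically perfect fit (mean squared residual below 1e-12) returns
    the −inf sentinel rather than a rounding-noise-dependent large negative
    number.
    """
    if rss <= 0.0 or rss / n < 1e-12:
        return float("-inf")
    return n * math.log(rss / n) + 2 * (n_params + 1)


# ---------------------------------------------------------------------------
# Energy budget and productivity index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CanopyEnergyParams:
    """Inputs of the canopy energy budget.

    S_t: incident solar radiation over the period (MJ m⁻²); epsilon_i /
    epsilon_c: interception and conversion efficiencies (0–1); k: energy
    content of plant mass (MJ g⁻¹); eta: harvest index (0 < η ≤ 1).
    """

    S_t: float
    epsilon_i: float
    epsilon_c: float
    k: float
    eta: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.epsilon_i <= 1.0:
            raise ArgumentError("epsilon_i must be within [0, 1]")
        if not 0.0 <= self.epsilon_c <= 1.0:
            raise ArgumentError("epsilon_c must be within [0, 1]")
        if self.k <= 0.0:
            raise ArgumentError("energy content k must be > 0")
        if not 0.0 < self.eta <= 1.0:
            raise ArgumentError("harvest index eta must be in (0, 1]")


def primary_production(p: CanopyEnergyParams) -> float:
    """Above-ground biomass P_n = S_t·ε_i·ε_c / k (g m⁻²)."""
    return p.S_t * p.epsilon_i * p.epsilon_c / p.k


def yield_potential(P_n: float, eta: float) -> float:
    """Yield potential Y_p = η·P_n; η is the harvest index."""
    if not 0.0 < eta <= 1.0:
        raise ArgumentError("harvest index eta must be in (0, 1]")
    return eta * P_n


@dataclass(frozen=True)
class ProductivityInputs:
    """Inputs of the growth index I_g for one period.

    R_i: mean daily radiation (MJ m⁻²); T_i: mean daily temperature (°C);
    T_b: base temperature (°C); RIX: radiation-interception factor, 1 under
    full leaf cover (LAI ≳ 2–3).
    """

    R_i: float
    T_i: float
    T_b: float = 5.0
    RIX: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.RIX <= 1.0:
            raise ArgumentError("RIX must be in (0, 1]")


def productivity_index(
    inp: ProductivityInputs, form: Literal["quotient", "product"] = "quotient"
) -> float:
    """Growth index I_g for one growth period.

    The default 'quotient' form is the photothermal quotient
    R_i / (T_i − T_b) · RIX — potential growth per unit of development,
    under which cooler bright seasons score as more productive.  The
    literal 'product' reading R_i·(T_i − T_b)·RIX is exposed for
    comparison.  Undefined (error, never infinity) when T_i ≤ T_b.
    """
    if inp.T_i <= inp.T_b:
        raise ArgumentError(
            f"growth index undefined: mean temperature {inp.T_i} °C not above "
            f"base {inp.T_b} °C"
        )
    if form == "quotient":
        return inp.R_i / (inp.T_i - inp.T_b) * inp.RIX
    if form == "product":
        return inp.R_i * (inp.T_i - inp.T_b) * inp.RIX
    raise ArgumentError(f"unknown productivity index form {form!r}")


# ---------------------------------------------------------------------------
# Three-parameter logistic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticParams:
    """Asym (upper asymptote, response units), xmid and scal (°C d)."""

    Asym: float
    xmid: float
    scal: float

    def __post_init__(self):
        if self.scal == 0.0:
            raise ArgumentError("scal must be nonzero")


def logistic_value(x, p: LogisticParams):
    """f(x) = Asym / (1 + exp((xmid − x)/scal)); vectorised over x."""
    z = (p.xmid - np.asarray(x, dtype=float)) / p.scal
    return p.Asym * special.expit(-z)


def _logistic_residual_jac(theta: np.ndarray, x: np.ndarray):
    """Model values and Jacobian columns (dA, dxmid, dscal) at theta."""
    A, xmid, scal = theta
    z = (xmid - x) / scal
    s = special.expit(-z)  # 1 / (1 + e^z)
    w = s * (1.0 - s)
    f = A * s
    jac = np.column_stack((s, -A * w / scal, A * w * z / scal))
    return f, jac


def _selfstart_logistic(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """SSlogis-style starting values: logit of the scaled response vs x."""
    asym0 = 1.05 * float(np.max(y))
    yscaled = np.clip(y / asym0, 1e-6, 1.0 - 1e-6)
    logit = np.log(yscaled / (1.0 - yscaled))
    slope, intercept = np.polyfit(x, logit, 1)
    if slope == 0.0:
        slope = 1e-6
    return np.array([asym0, -intercept / slope, 1.0 / slope])


@dataclass(frozen=True)
class LogisticFit:
    """A converged single-group logistic fit with asymptotic standard errors."""

    params: LogisticParams
    se: LogisticParams
    rss: float
    sigma2: float
    n: int
    aic: float
    n_iter: int

    def predict(self, x):
        return logistic_value(x, self.params)


def fit_logistic(
    x: Sequence[float],
    y: Sequence[float],
    start: LogisticParams | None = None,
    max_iter: int = 200,
    xtol: float = 1e-8,
) -> LogisticFit:
    """Nonlinear least squares fit of the three-parameter logistic.

    Self-starts from a logit regression of the scaled response unless
    ``start`` is given.  Raises :class:`FitError` (carrying the last
    iterate) on non-convergence and :class:`ArgumentError` on degenerate
    input (fewer than 5 points, constant x or constant y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ArgumentError("x and y must be 1-d arrays of equal length")
    if len(x) < 5:
        raise ArgumentError("at least 5 points required")
    if np.ptp(x) == 0.0:
        raise ArgumentError("x is constant")
    if np.ptp(y) == 0.0:
        raise ArgumentError("y has no spread")

    theta0 = (
        np.array([start.Asym, start.xmid, start.scal])
        if start is not None
        else _selfstart_logistic(x, y)
    )

    def resid(theta):
        f, _ = _logistic_residual_jac(theta, x)
        return f - y

    def jac(theta):
        _, j = _logistic_residual_jac(theta, x)
        return j

    res = optimize.least_squares(
        resid, theta0, jac=jac, method="lm", xtol=xtol, ftol=xtol,
        gtol=1e-12, max_nfev=max_iter * 10,
    )
    if not res.success:
        raise FitError(
            f"logistic fit did not converge: {res.message}",
            last_params=LogisticParams(*res.x),
        )
    n, p = len(x), 3
    rss = float(2.0 * res.cost)
    sigma2 = rss / max(n - p, 1)
    cov = sigma2 * np.linalg.inv(res.jac.T @ res.jac)
    se = np.sqrt(np.diag(cov))
    return LogisticFit(
        params=LogisticParams(*map(float, res.x)),
        se=LogisticParams(*map(float, se)),
        rss=rss,
        sigma2=sigma2,
        n=n,
        aic=aic_from_rss(rss, n, p),
        n_iter=int(res.nfev),
    )


# ---------------------------------------------------------------------------
# Season-grouped logistic
# ---------------------------------------------------------------------------

Structure = Literal["all_shared", "shared_scal", "all_separate"]
_STRUCTURE_ORDER: tuple[Structure, ...] = ("all_shared", "shared_scal", "all_separate")


def _n_params(structure: Structure, k: int) -> int:
    return {"all_shared": 3, "shared_scal": 2 * k + 1, "all_separate": 3 * k}[structure]


def _unpack(structure: Structure, theta: np.ndarray, k: int):
    """Per-group (Asym, xmid, scal) triples from the packed vector."""
    if structure == "all_shared":
        return [(theta[0], theta[1], theta[2])] * k
    if structure == "shared_scal":
        return [(theta[g], theta[k + g], theta[2 * k]) for g in range(k)]
    return [(theta[3 * g], theta[3 * g + 1], theta[3 * g + 2]) for g in range(k)]


def _grouped_resid_jac(structure: Structure, theta, x, gidx, k, n):
    triples = _unpack(structure, np.asarray(theta), k)
    f = np.empty(n)
    jac = np.zeros((n, len(theta)))
    for g in range(k):
        mask = gidx == g
        fg, jg = _logistic_residual_jac(np.array(triples[g]), x[mask])
        f[mask] = fg
        if structure == "all_shared":
            cols = (0, 1, 2)
        elif structure == "shared_scal":
            cols = (g, k + g, 2 * k)
        else:
            cols = (3 * g, 3 * g + 1, 3 * g + 2)
        for c, col in enumerate(cols):
            jac[mask, col] = jg[:, c]
    return f, jac


@dataclass(frozen=True)
class GroupedLogisticFit:
    """Selected season-grouped logistic fit plus the structure comparison.

    ``params``/``se`` map each group label to its (Asym, xmid, scal); under
    sharing the shared values repeat across groups.  ``comparison`` has one
    row per candidate structure (n_params, rss, aic) and extra-sum-of-
    squares F statistics for the two nested pairs.  ``candidates`` keeps
    every fitted structure for inspection.
    """

    structure: Structure
    groups: tuple[str, ...]
    params: Mapping[str, LogisticParams]
    se: Mapping[str, LogisticParams]
    rss: float
    sigma2: float
    aic: float
    n: int
    n_excluded: int
    comparison: pd.DataFrame
    candidates: Mapping[Structure, "GroupedCandidate"]


@dataclass(frozen=True)
class GroupedCandidate:
    """One candidate sharing structure fitted to the grouped data."""

    structure: Structure
    params: Mapping[str, LogisticParams]
    se: Mapping[str, LogisticParams]
    rss: float
    sigma2: float
    aic: float
    n_params: int


def _fit_structure(
    structure: Structure,
    x: np.ndarray,
    y: np.ndarray,
    gidx: np.ndarray,
    groups: tuple[str, ...],
    theta0: np.ndarray,
) -> GroupedCandidate:
    k, n = len(groups), len(x)

    def resid(theta):
        f, _ = _grouped_resid_jac(structure, theta, x, gidx, k, n)
        return f - y

    def jac(theta):
        _, j = _grouped_resid_jac(structure, theta, x, gidx, k, n)
        return j

    res = optimize.least_squares(
        resid, theta0, jac=jac, method="lm", xtol=1e-8, ftol=1e-8,
        gtol=1e-12, max_nfev=2000,
    )
    if not res.success:
        raise FitError(
            f"grouped logistic ({structure}) did not converge: {res.message}",
            last_params=res.x,
        )
    p = len(theta0)
    rss = float(2.0 * res.cost)
    sigma2 = rss / max(n - p, 1)
    cov = sigma2 * np.linalg.inv(res.jac.T @ res.jac)
    se_vec = np.sqrt(np.diag(cov))
    trip_est = _unpack(structure, res.x, k)
    trip_se = _unpack(structure, se_vec, k)
    params = {g: LogisticParams(*map(float, trip_est[i])) for i, g in enumerate(groups)}
    se = {g: LogisticParams(*map(float, trip_se[i])) for i, g in enumerate(groups)}
    return GroupedCandidate(
        structure=structure,
        params=params,
        se=se,
        rss=rss,
        sigma2=sigma2,
        aic=aic_from_rss(rss, n, p),
        n_params=p,
    )


def fit_grouped_logistic(
    x: Sequence[float],
    y: Sequence[float],
    group: Sequence[str],
    max_x: float = DEFAULT_MAX_THERMAL_TIME,
) -> GroupedLogisticFit:
    """Fit the three sharing structures across season groups and select one.

    Observations with thermal time ≥ ``max_x`` are excluded before fitting
    (strictly-below filter); the reported ``n`` reflects the exclusion.
    Selection: minimum AIC, with structures within 2 AIC units of the
    minimum collapsed onto the one with the fewest parameters.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    if not (len(x) == len(y) == len(group)):
        raise ArgumentError("x, y and group must have equal length")
    keep = x < max_x
    n_excluded = int((~keep).sum())
    x, y, group = x[keep], y[keep], group[keep]
    groups = tuple(sorted(str(g) for g in pd.unique(group)))
    group = group.astype(str)
    if len(groups) < 2:
        raise ArgumentError("at least 2 groups required after the thermal-time filter")
    gidx = np.searchsorted(np.array(groups), group)
    k, n = len(groups), len(x)

    per_group: list[LogisticFit] = []
    for g in range(k):
        mask = gidx == g
        if mask.sum() < 5:
            raise ArgumentError(
                f"group {groups[g]!r} too small after filtering ({int(mask.sum())} points)"
            )
        per_group.append(fit_logistic(x[mask], y[mask]))

    pooled = fit_logistic(x, y)
    starts: dict[Structure, np.ndarray] = {
        "all_shared": np.array([pooled.params.Asym, pooled.params.xmid, pooled.params.scal]),
        "shared_scal": np.concatenate(
            [
                [f.params.Asym for f in per_group],
                [f.params.xmid for f in per_group],
                [float(np.mean([f.params.scal for f in per_group]))],
            ]
        ),
        "all_separate": np.concatenate(
            [[f.params.Asym, f.params.xmid, f.params.scal] for f in per_group]
        ),
    }

    candidates = {
        s: _fit_structure(s, x, y, gidx, groups, starts[s]) for s in _STRUCTURE_ORDER
    }

    rows = []
    for s in _STRUCTURE_ORDER:
        c = candidates[s]
        rows.append(
            {"structure": s, "n_params": c.n_params, "rss": c.rss, "aic": c.aic}
        )
    comparison = pd.DataFrame(rows).set_index("structure")
    # extra-sum-of-squares F tests for the nested pairs
    for simple, complex_ in (("all_shared", "shared_scal"), ("shared_scal", "all_separate")):
        cs, cc = candidates[simple], candidates[complex_]
        df1 = cc.n_params - cs.n_params
        df2 = n - cc.n_params
        fstat = ((cs.rss - cc.rss) / df1) / (cc.rss / df2) if df2 > 0 else np.nan
        comparison.loc[complex_, "F_vs_simpler"] = fstat
        comparison.loc[complex_, "p_vs_simpler"] = (
            float(stats.f.sf(fstat, df1, df2)) if np.isfinite(fstat) else np.nan
        )

    min_aic = min(candidates[s].aic for s in _STRUCTURE_ORDER)
    selected = next(
        s for s in _STRUCTURE_ORDER if candidates[s].aic <= min_aic + AIC_PARSIMONY_MARGIN
    )
    chosen = candidates[selected]
    return GroupedLogisticFit(
        structure=selected,
        groups=groups,
        params=chosen.params,
        se=chosen.se,
        rss=chosen.rss,
        sigma2=chosen.sigma2,
        aic=chosen.aic,
        n=n,
        n_excluded=n_excluded,
        comparison=comparison,
        candidates=candidates,
    )


def simulate_grouped_logistic(
    truth: Mapping[str, LogisticParams],
    n_per_group: int,
    noise_sd: float,
    x_range: tuple[float, float] = (700.0, 1080.0),
    seed: int | None = None,
):
    """Draw (x, y, group) arrays from per-group logistic curves.

    Thermal times are Uniform over ``x_range`` and noise is additive
    Gaussian with standard deviation ``noise_sd``; used by parameter- and
    structure-recovery simulations.
    """
    rng = np.random.default_rng(seed)
    xs, ys, gs = [], [], []
    for label in sorted(truth):
        p = truth[label]
        x = rng.uniform(x_range[0], x_range[1], n_per_group)
        y = logistic_value(x, p) + rng.normal(0.0, noise_sd, n_per_group)
        xs.append(x)
        ys.append(y)
        gs.append(np.full(n_per_group, label))
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(gs)
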