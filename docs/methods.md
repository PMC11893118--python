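# Methods

`cropclock` derives phenology-anchored agro-meteorological variables from
daily weather and fits the statistical models used to predict green-bean
(*Phaseolus vulgaris* L.) growth durations and fresh pod yield in
subtropical production systems. This note records the models, conventions
and design choices so results can be interpreted and reproduced.

## Thermal time and windowed variables

Thermal time (growing degree days) is the crop's developmental clock.
The daily contribution is

    dd(t) = max(0, (min(tmax_t, T_cap) + tmin_t) / 2 − T_base)

with defaults `T_base` = 5 °C and `T_cap` = 30 °C, the convention for
field-grown beans on daily temperatures. Two conventions are deliberately
pinned down because different packages disagree:

- the cap is applied to `tmax` **before** averaging with `tmin`, and the
  daily value truncates at zero; `tmin` is **not** floored at the base.
  Both choices sit behind `DegreeDayRule`, so an alternative convention is
  a one-line change;
- stress days count days whose maximum temperature **strictly** exceeds
  the threshold (27.5 °C or 30 °C, the levels associated with flower and
  pod abortion). Strict-versus-inclusive is undocumented in the sources
  this package follows; strict was chosen and is stated here because the
  two differ on days exactly at a threshold.

Windows are anchored on phenology dates. An anchor-to-anchor window spans
`[start_anchor + 1 day, end_anchor]`, so its day count equals the plain
date difference — a sowing on 19 Feb with petal fall on 1 Apr gives a
41-day vegetative window, matching how growth durations are reported.
Fixed-length windows after an anchor start the day after it; windows
before an anchor end the day before it. Durations are plain date
differences: vegetative = petal fall − sowing, pod fill = harvest − petal
fall, total = their sum.

Sowing date is encoded as day of the Australian financial year
(1 July = day 1), which makes the covariate continuous across the
southern-hemisphere growing season instead of wrapping at 31 December.

Season labels: North-East Queensland (Bowen) sowings form the single
"Middle" season; South-East Queensland sowings split by month into
"Autumn" (January–July by default) and "Spring" (August–December). The
published descriptions of the sowing calendar differ slightly (one gives
Spring as Oct–Dec and Autumn as Jan–May; the field-conditions table gives
sowing months Mar–May and Aug–Nov), so the month map is a configurable
argument and the default is chosen so that every calendar month
classifies.

Missing features are explicit `NaN`s with a logged reason, never silent
zeros, so model fitting can apply complete-case analysis reproducibly.

## Synthetic weather

No weather accession ships with the package; the generator produces the
study conditions offline. Daily maximum temperature follows a sinusoidal
annual cycle with a mid-January (austral summer) peak plus independent
Gaussian noise; the minimum is the maximum minus a diurnal offset plus
noise, clamped so `tmin ≤ tmax`; radiation and vapour pressure follow
in-phase sinusoids clamped at physical floors; rain is an occasional
exponential draw. Defaults (mean tmax 26.5 °C, amplitude 5.5 °C, diurnal
offset 10.5 °C, daily noise sd 2.5 °C, mean radiation 18 MJ m⁻²,
amplitude 7 MJ m⁻², vapour pressure 18 ± 7 hPa) are set to resemble a
Lockyer-Valley-like South-East Queensland site, with summer maxima that
regularly cross the 27.5 °C and 30 °C stress thresholds.

What the generator does *not* emulate: autocorrelated synoptic weather
(each day's noise is independent), heat waves with realistic persistence,
rain–temperature coupling, and long-term warming trends. Tests passing on
this weather therefore demonstrate the correctness of the derivation and
modelling machinery under realistic marginal distributions, not
predictive skill on real station data.

## Productivity indices

The canopy energy budget gives primary production `P_n = S_t·ε_i·ε_c/k`
(incident radiation × interception efficiency × conversion efficiency /
energy content) and yield potential `Y_p = η·P_n` with harvest index η.
The per-period growth index is implemented as the photothermal quotient

    I_g = R_i / (T_i − T_b) · RIX

mean daily radiation per unit of mean temperature above base, scaled by
the radiation-interception factor RIX (1 under full leaf cover, LAI ≳
2–3). The typeset source formula is ambiguous between this ratio and the
product `R_i·(T_i − T_b)`; the quotient reading was adopted because the
surrounding interpretation (a cooler, brighter season is *more*
productive via "a more favourable radiation to temperature balance") only
holds for the ratio. The product reading remains available via
`productivity_index(..., form="product")`. The index is undefined (an
error, never ±inf) when mean temperature does not exceed the base.

## Grouped logistic pod growth

Fresh pod weight against thermal time after petal fall follows the
three-parameter logistic `f(x) = Asym / (1 + exp((xmid − x)/scal))`.
Observations with thermal time ≥ 1080 °C d are excluded before fitting
(strictly-below filter): past that point pods turn stringy and fresh
weight is beyond its optimum, so the data leave the growth curve.

Fitting is nonlinear least squares (Levenberg–Marquardt via
`scipy.optimize.least_squares`) with the analytic Jacobian of the
logistic, relative tolerance 1e-8, and a self-start in the style of
`SSlogis`: scale the response by 1.05·max(y), regress its logit on x, and
read off initial `xmid` and `scal`. Standard errors are the usual
asymptotic `σ²(JᵀJ)⁻¹` diagonal. Non-convergence raises an error carrying
the last iterate.

Season-grouped data are fitted under three nested sharing structures:
all three parameters shared; separate `Asym` and `xmid` per season with a
common `scal`; and all parameters separate. Model choice uses
`AIC = n·ln(RSS/n) + 2·(p+1)` with a parsimony margin: among structures
within 2 AIC units of the minimum, the fewest-parameter structure is
selected. The margin implements the standard view that models within
~2 AIC units are statistically indistinguishable, in which case the
simpler model is favoured; without it, a one-parameter-larger structure
would be selected whenever a χ²₁ noise fluctuation exceeds 2, i.e. in
roughly one replicate in six even when the simpler structure is true.
The full comparison table (AIC, extra-sum-of-squares F and p for the
nested pairs) and every candidate fit are returned so the raw-AIC choice
can always be inspected.

## Duration models

Durations are modelled as continuous days by ordinary least squares on
the shipped candidate catalogues (per response × season: sowing day,
thermal times, window means of temperature/radiation/vapour pressure,
cumulative radiation, stress-day counts). The pipeline:

1. **Collinearity screen** — candidate pairs are scanned in catalogue
   order and the later-listed member of any pair with |Pearson r| ≥ 0.95
   is dropped (constant columns drop first); deterministic given the
   order.
2. **Backward stepwise AIC** — from the full model, repeatedly remove the
   single variable whose removal most lowers the AIC (ties toward the
   later-listed variable); stop when no removal lowers it. The
   complete-case rows of the full model are frozen at the start so every
   AIC in the search is computed on the same n. The accepted-step AIC
   sequence is non-increasing by construction and is returned as a trace.
3. **Prediction intervals** — t-based intervals (default 80 % coverage)
   including both residual variance and the leverage term, delegated to
   `statsmodels` `get_prediction`.

The AIC convention drops additive constants, so values differ from other
software by a constant that cancels within any comparison made here. A
numerically perfect fit (mean squared residual < 1e-12) reports the −inf
sentinel. OLS itself is `statsmodels.OLS`; its coefficients are checked
against a direct normal-equations solve in the test suite.

## Yield components

Fresh pod yield decomposes as plants per area × pods per plant × pod
weight. Two estimators are provided: the per-sample estimator (mean of
per-quadrat pod mass scaled to kg/ha — the unit conversion is fixed as
kg/ha = g × 10 / area_m² and unit-tested) and the product-of-means
estimator with a first-order delta-method standard error,
`se = mean·√Σ(seᵢ/meanᵢ)²`, assuming independent components (no
covariances are available). The two estimators agree exactly only when
all quadrats are identical; on real samples the per-quadrat products
include covariance terms the product of means does not, and both are
reported. The delta approximation is validated against Monte Carlo to
within 10 % for component CVs ≤ 0.15, its first-order validity regime.

Maturity proportions are simple ratios (current pod weight over the
4.91 g mature marketable reference, with the 4.9 g tabulated variant
selectable; sampled over final yield), reported to 3 decimals.

The sampling-size rule is z-based (not t-based):
`n = ⌈(z·CV/rel_error)²⌉` with the CV recovered from the standard error
of the mean, floored at 1. Applied to observed pods-per-plant variation
(mean 15.58, se 0.83 from 11 quadrats) it gives 12 samples for a ±10 %
estimate at 95 % confidence, the lower end of the 12–15 recommendation;
the z-form was chosen because it reproduces that recommendation.

## Sowing-date scans

`scan_sowings` lays a grid of hypothetical sowing dates (default step
1 day) per location, assigns each season-specific fixed durations
(default 41 d vegetative, 21 d pod fill — near the observed medians), and
derives the full feature table. Model-predicted durations are an opt-in
two-pass mode (features from provisional fixed windows → predicted
durations → final windows), kept optional to avoid circularity when the
scan feeds the same models. Sowings whose windows run past the weather
coverage are dropped with a logged count.

Percentile summaries report n, the 20th percentile, median and 80th
percentile per group × variable using linear interpolation between
closest ranks (numpy default, R type 7); the convention is stated because
published percentile tables cannot adjudicate it.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is reproducible.
The recovery simulations use 500 points per season with Gaussian noise
sd 800 on thermal times Uniform(700, 1080) °C d, the scale at which the
logistic parameters are well identified (asymptote se ≈ 60, scal se ≈ 1);
structure- and parameter-recovery rates are measured over 100 seeded
replicates. Prediction-interval calibration uses 2000 held-out draws;
delta-method validation uses 10⁵ Monte-Carlo draws; property checks run
over 200 randomized windows. Synthetic weather spans 3–10 years daily.

## Known limitations

- The degree-day tmin-floor question and stress-day strictness are
  conventions, not certainties; both are isolated and documented above.
- Duration-model candidate catalogues reproduce the published variable
  lists, but the exact variable subsets behind the published per-field
  predictions are not fully recoverable; the catalogues are shipped as
  editable configuration.
- The logistic response is unit-agnostic ("response units"); the fitted
  asymptote scale depends on how fresh weight was recorded.
- No gap-filling of real weather records: missing daily values are hard
  errors, because no imputation rule is defined for these analyses.
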