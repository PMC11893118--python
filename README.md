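# cropclock

Agro-meteorological derivation and statistical models for predicting
green-bean (*Phaseolus vulgaris* L.) maturity and fresh pod yield in
subtropical production systems.

Commercial fresh-market beans are sown across a long window of dates and
several locations; growers need to know when each sowing will reach petal
fall and optimum harvest, and how much marketable fresh weight to expect.
`cropclock` turns recorded crop phenology (sowing, petal fall, harvest
dates) plus daily weather into the variables and models that answer those
questions:

- **Thermal time** as growing degree days with base/cap truncation
  (default base 5 °C, cap 30 °C): `dd = max(0, (min(tmax, 30) + tmin)/2 − 5)`,
  summed over phenology-anchored windows.
- **Windowed weather variables**: stress-day counts above 27.5 °C / 30 °C,
  cumulative and mean radiation, temperature and vapour-pressure means,
  over vegetative (sowing → petal fall), pod-fill (petal fall → harvest)
  and fixed post-anchor windows.
- **Photothermal productivity index** `I_g = R_i/(T_i − T_b)·RIX` and the
  canopy energy budget `P_n = S_t·ε_i·ε_c/k`, `Y_p = η·P_n`.
- **Season-grouped logistic pod growth**: fresh weight vs thermal time
  under `f(x) = Asym/(1 + exp((xmid − x)/scal))`, comparing shared /
  shared-scal / separate parameter structures by AIC with a parsimony
  margin, restricted to thermal times below 1080 °C d.
- **Duration models**: collinearity screening, backward stepwise-AIC
  ordinary least squares, and 80 % t-based prediction intervals.
- **Yield components**: plants per area × pods per plant × pod weight,
  delta-method error propagation, maturity proportions and the z-based
  minimum-sample-size rule.
- **Sowing-date scans**: hypothetical sowing grids over years × locations
  with median / 20th / 80th percentile summaries.

A seeded synthetic weather generator emulates South-East Queensland
seasonality (southern-hemisphere sinusoidal annual cycles with daily
noise), so every stage runs offline. Real SILO-style daily CSV exports
are read directly. See `docs/methods.md` for model details and
conventions.

## Worked example

```python
import datetime as dt
import cropclock as cc

# ten seasons of synthetic SEQ weather, then derive one sowing's variables
weather = {"gatton": cc.simulate_weather(
    cc.SyntheticWeatherParams(seed=1), dt.date(2014, 7, 1), 1200, "gatton")}
rec = cc.CropRecord("r1", "gatton", "SEQ", sowing=dt.date(2015, 2, 19),
                    petal_fall=dt.date(2015, 4, 1), harvest=dt.date(2015, 4, 22),
                    fresh_yield=12092.0)
row = cc.build_feature_table([rec], weather).iloc[0]
print(row["season"], row["duration_veg"], row["duration_pod"])
print(round(row["thermal_time_veg"], 1), round(row["thermal_time_pod"], 1),
      row["stress27_pod"])
```

prints

```
Autumn 41 21
747.9 334.6 8.0
```

an Autumn sowing with a 41-day vegetative and 21-day pod-fill period that
accumulated 747.9 °C d of thermal time to petal fall, 334.6 °C d during
pod fill, and saw 8 pod-fill days above the 27.5 °C stress threshold.

Fitting the season-grouped logistic to simulated fresh-weight data:

```python
truth = {"Autumn": cc.LogisticParams(6064, 876, 22),
         "Spring": cc.LogisticParams(6371, 836, 22)}
x, y, g = cc.simulate_grouped_logistic(truth, 500, noise_sd=800.0, seed=1)
fit = cc.fit_grouped_logistic(x, y, g, max_x=1080)
print(fit.structure, fit.n)
for season, p in fit.params.items():
    print(season, round(p.Asym, 1), round(p.xmid, 1), round(p.scal, 2))
```

```
shared_scal 1000
Autumn 6068.6 876.9 21.87
Spring 6472.2 836.9 21.87
```

The fitter identifies the generating structure — separate asymptotes and
inflection points with a common scale — and recovers the parameters
within sampling error. And the sampling-size rule: estimating
pods-per-plant (observed mean 15.58, se 0.83 from 11 quadrats) to within
10 % at 95 % confidence needs

```python
cc.required_sample_size(15.58, 0.83, 11)   # -> 12
```

## Command line

```bash
cropclock simulate-weather --start 2014-07-01 --days 3650 --seed 1 --out weather/gatton.csv
cropclock derive --crops crops.csv --weather weather/ --out features.csv
cropclock fit-duration --features features.csv --response duration_pod --out model.json
cropclock fit-logistic --features features.csv --x thermal_time_total --out fit.json
cropclock yield-components --samples samples.csv --final-yield 10578 --out report.json
cropclock scan --weather weather/ --start 2015-01-01 --end 2015-12-31 --out scan.csv
cropclock summarize --rows scan.csv --variables thermal_time_veg,stress27_pod --out summary.csv
```

Each command writes a `<out>.manifest.json` recording inputs, parameters
and the package version.

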