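# heatrisk

Forecasting heat-related ambulance transportations from the daily maximum
wet-bulb globe temperature (WBGT), for epidemiologists and public-health
planners who need long-term baseline scenarios of heatstroke burden under
climate change.

Daily heatstroke transport counts rise sharply once the daily maximum WBGT —
a composite heat-stress index combining temperature, humidity, solar
radiation and wind — crosses an age-group-specific threshold. `heatrisk`
fits threshold dose–response models to daily count data by Poisson maximum
likelihood, selects among them by AIC, and projects the fitted risk onto
future climate-scenario WBGT series and age-specific population
trajectories, with parametric-bootstrap confidence intervals.

## The model

Let `T` be the daily maximum WBGT (°C) and `n(T)` the expected number of
transports per million population per day. Three dose–response shapes are
supported, each continuous at its estimated threshold(s):

* **hockey stick** — `n(T) = β₁` for `T < T_w`, `β₁ + β₂(T − T_w)` above;
* **two-step hockey stick** — thresholds `T_w1 < T_w2` with gradients `β₂`
  then `β₃`;
* **exponential** — `n(T) = β₁` below `T_w`, `β₁·exp(r(T − T_w))` above.

Observed daily counts are Poisson with mean `n(T) × population / 10⁶`.
Thresholds enter a profile grid (default 0.1 °C); the remaining parameters
are maximised analytically-gradient quasi-Newton at each grid point. AIC
(`2k − 2·loglik`, thresholds counted as free parameters, so k = 3/5/3)
ranks the models. Uncertainty is propagated by drawing the non-threshold
parameters from a multivariate normal with the inverse observed-information
covariance (5,000 draws, 2.5/97.5 percentiles by default).

The daily maximum WBGT itself is approximated from standard meteorology by
the regression formula used operationally in Japan:

```
WBGT = 0.735·Tmax + 0.0374·RH + 0.00292·Tmax·RH + 7.619·SR − 4.557·SR² − 0.0572·WS − 4.064
```

with `Tmax` in °C, `RH` in %, `SR` in kW/m² and `WS` in m/s. Days are
classified into the five heat-alert bands (<21, 21–25, 25–28, 28–31,
≥31 °C); band occupancy is summarised over 5-year windows, and risk is
accumulated only over the May 1 – September 30 season (153 days).

## Worked example

Fit the three models to five synthetic observation years at Tokyo-like
magnitudes (3.08 million people aged 65+, thousands of seasonal transports
per year), then project the best model onto a warming century:

```python
import heatrisk as hr

climate = hr.simulate_climate(hr.ClimateScenarioSpec(2015, 2019, seed=42))
cases = hr.simulate_cases(climate, hr.tokyo_like_truth(), seed=42)

fits = [hr.fit_model(cases, kind, grid_step=0.5, age_group="65+")
        for kind in ("hockey", "two_step", "exponential")]
best = hr.compare_models(fits)
```

which prints (per model, then the AIC winner):

```
hockey       AIC= 3193.2
two_step     AIC= 2939.0
exponential  AIC= 2867.9
best: exponential  tw=22.5 C  r=0.43/C  beta1=0.38/million/day
```

The exponential model wins decisively, recovering the generating truth
(threshold 22.7 °C, rate 0.43/°C, baseline 0.4/million/day). Projecting it
onto a 0.5 °C/decade warming scenario and a 1 %/year-growing elderly
population:

```python
scenario = hr.simulate_climate(hr.ClimateScenarioSpec(
    2000, 2099, trend_c_per_decade=0.5, noise_sd=1.5, seed=42))
pop = hr.simulate_population(hr.TruthSpec(
    params={"65+": best.params}, base_population={"65+": 3.08e6},
    growth_rate={"65+": 0.01}, start_year=2015), range(2000, 2100))
draws = hr.bootstrap_params(best, 5000, seed=42)
proj = hr.fold_change(hr.projection_ci(best, draws, scenario, pop[["year", "population"]]), 2000)
```

```
 window_start  expected_count  ci_low  ci_high  fold_vs_baseline
         2085          8853.7  8390.7   9322.5              13.8
         2090          9854.4  9330.2  10385.5              15.4
         2095         11833.1 11160.1  12518.0              18.4
```

`expected_count` is the mean expected annual number of transports per
5-year window; the interval is the 2.5–97.5 percentile range of the
bootstrap draws; `fold_vs_baseline` compares each window with 2000–2004.
The exponential dose–response compounds warming and demography into a
steeply growing burden.

The same workflow is available from the shell via the `heatrisk` CLI
(`heatrisk simulate`, `heatrisk fit`, `heatrisk wbgt bands|trend`,
`heatrisk project`, `heatrisk run --config run.yaml`).

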