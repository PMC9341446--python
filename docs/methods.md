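# Methods

## Scope and data model

`heatrisk` links daily maximum wet-bulb globe temperature (WBGT) to daily
counts of heat-related ambulance transportations per million population,
and projects the fitted relationship onto future climate scenarios and
age-specific population trajectories. The pipeline has four stages:

1. **WBGT and alert bands** (`heatrisk.wbgt`) — approximate the daily
   maximum WBGT from meteorology, classify days into the five Japanese
   heat-alert bands, and summarise band occupancy over multi-year windows.
2. **Dose–response fitting** (`heatrisk.dose_response`) — Poisson maximum
   likelihood for three threshold models, AIC comparison, per-WBGT MAE
   diagnostics, parametric bootstrap.
3. **Projection** (`heatrisk.projection`) — seasonal risk accumulation,
   embedding onto projected populations, bootstrap intervals, fold-changes.
4. **Synthetic data** (`heatrisk.simulate`) — generators with the exact
   statistical structure the analysis assumes, so every stage is testable
   without external downloads.

`heatrisk.io` supplies CSV readers/writers, a validated run configuration
and the end-to-end pipeline; `heatrisk.cli` is a thin command-line layer.

## WBGT approximation and banding

The approximation
`WBGT = 0.735·Tmax + 0.0374·RH + 0.00292·Tmax·RH + 7.619·SR − 4.557·SR² − 0.0572·WS − 4.064`
takes Tmax in °C, RH in percent (validated to [0, 100]), SR in kW/m² and WS
in m/s. It is monotone increasing in Tmax (∂WBGT/∂Tmax = 0.735 + 0.00292·RH
> 0) and decreasing in WS. Because the commonest input error is solar
radiation in W/m², values of SR above 5 kW/m² raise a unit warning.

Band boundaries are **left-closed**: [21, 25), [25, 28), [28, 31), [31, ∞),
so 28.0 °C falls in the 28–31 band and "31 °C or more" is its own level,
matching the warning-system wording. Band occupancy is reported as the
proportion of days per consecutive, non-overlapping window (default 5
years), anchored at the first year of the series. **Feb 29 is dropped
everywhere**, so every year contributes exactly 365 days to every
denominator; series must cover whole, consecutive calendar years and a
partial trailing window is an error rather than a silently shortened one.

The per-window trend of a high-WBGT band ("≥28" sums the top two bands) is
the ordinary-least-squares slope of the window proportions (×100, so
percentage points) against window index — the simplest estimator consistent
with a single per-window rate of change. Endpoint differencing or mean
pairwise slopes would be alternatives; OLS is the recorded default.

## Dose–response models

With `T` the daily maximum WBGT and `n(T)` the expected transports per
million per day:

* hockey stick: `n(T) = β₁ + β₂·max(T − T_w, 0)`;
* two-step: `n(T) = β₁ + β₂·clip(T − T_w1, 0, T_w2 − T_w1) + β₃·max(T − T_w2, 0)`,
  with `T_w1 < T_w2` enforced with a minimum gap of one grid step;
* exponential: `n(T) = β₁·exp(r·max(T − T_w, 0))`.

All three are continuous at their thresholds by construction and
non-decreasing in `T` under the fitted constraints (β ≥ 0). The two-step
model with β₂ = β₃ reduces to the hockey stick; the exponential with r → 0
reduces to a constant.

**Likelihood.** Daily counts are Poisson with mean
`λ = n(T) × population/10⁶`, using the age group's population for that
calendar year. The likelihood is defined on **counts**, not on per-million
values: counts are the integers a Poisson distribution describes, while
per-million values are generally non-integer. A zero mean with a positive
count yields −∞ (signalled, not raised); a zero mean with a zero count
contributes nothing.

**Season.** By default only days from May 1 to September 30 (153 days)
enter the likelihood, mirroring the season over which risk is later
projected; `season=None` fits on all days.

**Optimisation.** The likelihood is non-differentiable in the thresholds,
so thresholds are profiled over a grid (default step 0.1 °C — the precision
at which thresholds are conventionally reported — spanning
[min(T) + 0.5, max(T) − 0.5]). Candidates need at least one observation in
every segment they define; inadmissible candidates are skipped. At each
grid point the remaining parameters are maximised by L-BFGS-B with analytic
gradients and bounds β₁ ≥ 10⁻⁹ (keeps λ > 0), β₂, β₃ ≥ 0, and
r ∈ [−2, 5] (a numerical guard far outside the plausible range for daily
heat risk). Warm starts from the previous grid point keep a full profile
fit in the 0.1–1 s range for five seasons of daily data. Optimiser failure
at the winning grid point is an error with diagnostics, not a silent
fallback.

**AIC.** `AIC = 2k − 2·loglik` with thresholds counted as estimated
parameters: k = 3 (hockey), 5 (two-step), 3 (exponential). Ties are broken
by fewest parameters, then by model declaration order (hockey, two-step,
exponential). The reported log-likelihood includes the `log y!` constant,
so AIC values are comparable across software.

**Covariance and bootstrap.** The covariance of the non-threshold
parameters is the inverse of a central-finite-difference observed
information at the optimum, symmetrised with negative eigenvalues clipped
(a pseudo-inverse handles near-singular fits). The parametric bootstrap
draws the non-threshold parameters from a multivariate normal centred at
the MLE with this covariance; draws violating β ≥ 0 are redrawn.
**Thresholds are held at their point estimates**: a normal approximation is
invalid for grid-profiled breakpoints, whose profile likelihood is
piecewise and non-smooth. A case-resampling bootstrap
(`bootstrap_params(..., method="case")`) is available when threshold
uncertainty must be propagated; it refits per replicate and is
correspondingly slower. Defaults follow the study conventions: 5,000
replicates, 2.5/97.5 percentiles.

**MAE diagnostics.** Observations are grouped by WBGT rounded to 0.1 °C
(the typical reporting precision of observed series); each group's MAE is
the mean absolute difference between observed and predicted per-million
values. The largest group MAE and its WBGT summarise where the model is
weakest — empirically the hottest days, where day-to-day behavioural
adaptation makes counts most variable.

## Projection

For each year the seasonal risk is the sum of `n(T)` over the 153 days of
May 1 – September 30 (missing seasonal days are an error listing the gaps);
the expected annual count is that sum times the year's population in
millions. Windows report the **mean annual count** per 5-year window by
default (`window_stat="sum"` gives totals): means keep the y-scale of
annual transports and remain comparable if window lengths ever differ.
Fold-changes divide each window's expected count by a baseline window's.

Fitting age groups (0–17, 18–64, 65+) are mapped onto the projection
age groups of published population tables (0–14, 15–64, 65+) as
0–17 → 0–14 and 18–64 → 15–64 — a deliberate, documented mismatch
inherited from the data sources, acceptable because the boundary cohort
(15–17-year-olds) contributes little to either group's risk. Populations
for years between tabulated projection years are linearly interpolated.

Bootstrap intervals re-run the projection map per parameter draw and take
empirical percentiles per window. The map is linear in β₁, β₂, β₃ for fixed
thresholds, so for the piecewise-linear models the interval is near-
symmetric about the point estimate; the exponential model's intervals are
mildly right-skewed, as expected.

## Synthetic data

The climate generator is
`wbgt(d) = level + amplitude·cos(2π(doy − peak)/365) + (trend/10)·(years since start) + ε`,
`ε ~ N(0, sd²)`. A cosine is the simplest smooth unimodal annual cycle;
nothing downstream depends on its exact shape. Defaults emulate Tokyo
daily-maximum WBGT: annual mean 14 °C, amplitude 13 °C, peak at day-of-year
205 (late July), day-to-day sd 2 °C — giving summer maxima in the upper 20s
with occasional days above 31 °C. The warming trend is injectable in
°C/decade (0 by default for observation-period fixtures; 0.5 °C/decade is
used as a mid-range warming scenario in the examples and acceptance run).

Case counts are drawn per day and age group as
`Poisson(n_true(T) × population/10⁶)` from a configurable truth; the
Tokyo-like truth uses exponential dose–response with thresholds lowest for
the elderly (22.7 °C for 65+, against 25.7/23.7 °C for the younger groups)
and populations 1.86 / 8.25 / 3.08 million with mild secular drift, which
yields seasonal 65+ totals in the low thousands per year — the magnitude of
the observed Tokyo system. Population trajectories are exact geometric
growth. A single seed fans out via `numpy.random.SeedSequence.spawn` to
independent climate/case streams, so every generator is a pure function of
its spec and seed and fixture bundles are byte-identical across runs.

What the generator deliberately does **not** emulate: heat-wave persistence
(noise is i.i.d., not autocorrelated), humidity–temperature covariance,
behavioural adaptation (variance inflation at high WBGT), or any spatial
structure. Passing tests therefore demonstrate correctness of the
estimators and pipeline under the model's own assumptions, not robustness
to the overdispersion and serial dependence real series exhibit.

## Problem sizes used in tests and the acceptance run

Monte-Carlo experiments use replicate studies of 5 seasons × 153 days at
3 million population: 100 replicates for parameter recovery and for
bootstrap-interval coverage, 100 for model-selection consistency in the
test suite (50 and 20 in the acceptance script, which also runs a full
century-scale projection). Model-selection experiments run all three models
on a 0.5 °C threshold grid: AIC ranking is insensitive to threshold
resolution, and the two-dimensional two-step profile at 0.1 °C would cost
two orders of magnitude more compute for no informational gain. Parameter
recovery keeps the default 0.1 °C grid.

## Known limitations

* No overdispersion (negative binomial), lag structure, or covariates
  beyond daily maximum WBGT; counts on hot days are empirically more
  variable than Poisson, so bootstrap intervals are anti-conservative there.
* Threshold uncertainty is not propagated by the default bootstrap (see
  above); threshold confidence statements require the case-resampling mode.
* The profile grid bounds ([min + 0.5, max − 0.5]) assume the data contain
  days on both sides of the true threshold; series entirely above or below
  it are rejected rather than extrapolated.
* Projections hold the fitted dose–response fixed for a century: no
  adaptation, acclimatisation, or policy response. They are baselines, not
  forecasts.
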