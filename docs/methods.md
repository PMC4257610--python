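# Methods

This note documents the models implemented in `mosqspec`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical conventions used throughout.

## Time-series conventions

All analyses operate on uniformly sampled series (`TimeSeries`) with an
explicit sampling interval `Δt` in days. Missing days are NaN gaps and are
never filled silently: weather gaps are linearly interpolated up to 7 days
(logged), abundance gaps either raise or are filled explicitly by the user
with `fill_gaps` (long gaps should instead split the series, since
interpolation injects spurious low-frequency power into spectra).

Moving averages are **trailing** (causal): the mean over the `w` days
ending at day *t*. Development and survival on day *t* cannot depend on
future weather; the first `w−1` days use the partial available window so
simulations can start on day 1.

## Power spectrum

The discrete Fourier transform is evaluated on the period grid
`T_i = N·Δt/i`, `i = 1 … N/2`. Power is `(2/N)²·|X_i|²`: the squared
amplitude of the sinusoidal component of period `T_i`, so a unit-amplitude
sinusoid on a grid frequency gives exactly unit peak power. Under this
normalisation each interior component of amplitude `A` contributes `A²/2`
to the series variance and the Nyquist component (even `N`) `A²/4`
(`PowerSpectrum.variance_from_spectrum` checks the identity). The mean
(`i = 0`) is removed by default (`detrend="mean"`); no taper is applied by
default (a Hann option exists and is flagged in the output), and abundance
is analysed untransformed by default with a `log(1+N)` option flagged when
used — both choices are exposed because the right answer is data-dependent.

Peak detection smooths the spectrum with a 3-bin moving average (raw
periodograms of noisy series are jagged; width configurable, 1 disables),
finds local maxima — plateaus produced by the smoothing kernel are
admitted at their edges — and refines each candidate to the largest
raw-power bin among its immediate neighbours. Ranking is by raw power,
ties broken toward the longer period.

## Correlograms and weekly subsampling

The ACF uses the biased (1/n) normalisation — standard, and it keeps the
sample autocovariance sequence positive semidefinite, which the
Durbin–Levinson recursion behind the PACF requires (both delegated to
statsmodels, `pacf(method="ldb")`). The 95 % band is the large-sample
white-noise approximation `±1.96/√n`; no bandwidth correction is applied.
Winter zeros are retained — no exclusion rule is imposed — and
"significantly positive out to L" statements are operationalised by
`significant_positive_run`: the longest initial run of lags above the
positive band, reported in days.

`weekly_subsample` splits a daily series into the 7 series collected on a
fixed weekday (`Δt = 7`), which together partition the input. Any
structure with period below 14 days is unresolvable in every subsample
(Nyquist), and the apparent memory of the series varies strongly with the
weekday sampled.

## Individual-based simulator

Three stages: egg, larva/pupa, adult. Individuals created on the same day
in the same stage with the same sampled residence time form one cohort;
cohorts are thinned binomially each day, statistically identical to
per-individual simulation. Internally each stage is a count array indexed
by days-remaining, so one simulated day is a handful of vectorised draws;
residence times are sampled by multinomial allocation over the exact
probability mass function of the rounded (trunc-)normal, equivalent to
rounding per-individual normal draws.

Daily order of operations: (1) survival thinning per stage; (2)
development-clock decrement, frozen for the overwintering stage (eggs for
*Ae. vexans*, larvae for *Cs. melanura*) while the 10-day mean temperature
is below the diapause threshold; (3) transitions for cohorts reaching zero
days — egg hatch is gated by inundation (daily rain ≥ 5 mm) for the
floodwater species when rainfall effects are on; (4) gonotrophic
completions: a Bernoulli blood-meal/oviposition trial, on success a normal
egg batch whose mean grows with the day's rainfall, halved by the 0.5
female fraction; survivors immediately begin a new cycle, until death.

Stage residence times follow `d = A·T^(−a)` on the trailing 10-day mean
temperature with sd 1 day, rounded to whole days and floored at 1. `T` is
clamped at +1 °C before the power law (which diverges at 0); genuinely
cold conditions are handled by the diapause freeze, not the clamp.
Exponents are literature values (1.90 / 1.86 for *Ae. vexans* embryo and
larva; 0.30 / 2.25 for *Cs. melanura* — the anomalously small 0.30 is kept
as published and is one YAML line to change). The `A` coefficients are
documented stand-ins anchored to stage-duration targets: *Ae. vexans*
embryogenesis ≈ 3 d and larva→adult ≈ 8 d at 25 °C (consistent with
generation turnover under three weeks in favourable conditions);
*Cs. melanura* larval development months-long in its cool swamp
micro-habitat, ≈ 165 d at 18 °C (≈ 80 d at 25 °C).

Survival is a downward parabola in the 10-day mean temperature,
parameterised by (optimum, peak, half-width) rather than raw polynomial
coefficients; defaults peak near 24–25 °C. *Cs. melanura* larval survival
is 1 under zero crowding and wet conditions. Larval and adult survival is
multiplied by a dryness penalty when 10-day mean precipitation falls below
1 mm/day (0.9 for the floodwater species; 0.97 for the swamp breeder,
whose crypts buffer dry spells). Egg and larval survival decline linearly
with the stage's own abundance (slopes in the species files); everything
clips to [0, 1]. The half-widths were widened until both species persist
through the cool season under the synthetic climate — a calibration of
stand-in values for demographic realism, not a fit to any count series
(no calibration to observations is performed anywhere in the simulator).

Blood-meal success is linear in 10-day mean relative humidity for
*Ae. vexans* and an increasing quadratic in 10-day mean temperature for
*Cs. melanura*, clipped to [0, 1].

Forcing configurations: `full_weather`; `temperature_only` (rainfall
effects on survival, oviposition and hatching off); `endogenous` (constant
temperature, default 18 °C, rainfall effects off, constant 70 % humidity).
Ensembles default to 20 replicates, replicate *r* seeded `seed + r`;
initial condition 500 overwintering-stage individuals; the first 365 days
are discarded as burn-in. All configurable.

Under the endogenous configuration the *Cs. melanura* ensemble oscillates
around a quasi-equilibrium with a dominant spectral period close to the
egg → oviposition loop length (≈ 5 + 165 + 15 ≈ 185 d at 18 °C): demographic
noise continually excites the renewal echo of the generational feedback.
The ~180-day design target for this quasi-cycle fixed the larval-duration
stand-in above; the emergent period is then measured, not asserted.

### Observation layer

Observed counts are `Binomial(adults_t, activity(rain_t))` (or the rounded
product in deterministic mode). The parametric activity curve is a
piecewise log-exponential hump: rising to 1 at an optimum rainfall
(default 2 mm/day), falling steeply above it, floored at 0.15 — the
qualitative shape recovered by the estimation side. Estimation:
`activity_ratio_series` divides each day's count by the maximum in a
**centered** 31-day window (a trailing option exists; the centered choice
makes "the best conditions of a homogeneous period" symmetric);
all-zero windows give undefined ratios, excluded so winters do not
contaminate the curve. `bin_by_rainfall` takes per-bin medians over
configurable rainfall intervals (default edges 0, 0.5, 1, 2, 5, 10, 20, ∞
mm/day — a logging-documented analysis choice, not an estimate).

## Density-dependent models

Both models are linear in the density term `D` (= `N` for Ricker, `log N`
for Gompertz) on the log-growth-rate scale, so calibration is OLS of
`log(N_{t+1}/N_t)` on `D_{t−lag}` (lags 0–5, multiple lags allowed) plus
additive environmental covariates; back-transformation gives `r_m` (the
intercept) and `K = −a/b` (Ricker) or `log K = −a/b` (Gompertz).
Transitions touching a zero count are dropped — the linearisation needs a
log ratio — and their number is always reported. Least squares on
ecological series can bias parameters; the fits here serve comparison of
correlation structures (the purpose the package puts them to), not
parameter inference, and no bias correction is applied. Simulation adds
Gaussian noise (default: the fit's residual sd) to the log growth rate.

A diagnostic contrast the test suite exercises: lag-0 density control
produces negative or insignificant short-lag PACFs in simulated series
(overcompensation needs `r_m > 1` for Ricker but `r_m > log K` for the
Gompertz form), whereas a mechanistic population observed through the
rainfall-driven activity layer keeps positive partial correlations out to
a week — two mechanisms distinguishable from a correlogram.

## Synthetic data

The weather generator produces an annual temperature sinusoid (period
365.25 d) plus AR(1) noise, wet/dry Bernoulli rainfall with exponential
depths, and humidity elevated on wet days. It deliberately omits storm
clustering, fronts and inter-annual variability: rainfall is white, so
activity-driven observation noise carries no multi-day memory of its own.
The abundance generator superposes sinusoidal periodicities on a baseline,
floors at zero, zeroes a winter window, and draws negative-binomial counts
(Gamma–Poisson mixture) around the expectation — Poisson noise cannot
produce the order-of-magnitude day-to-day swings daily traps record.
Passing tests on these generators therefore demonstrate the machinery and
its qualitative signatures, not distributional fidelity to any particular
station or trap site.

## Numerical choices and degenerate inputs

* All randomness flows from explicit `numpy.random.Generator` seeds; no
  global state. Pipelines fan one global seed out to per-stage seeds.
* Residence-time PMFs are cached per (stage, 0.1 °C-rounded temperature);
  support is capped at 400 days with the far tail lumped into the cap.
* `sd → 0` degenerates every sampler to its rounded mean; empty
  populations are absorbing; peak search excludes the mean component by
  construction of the period grid.
* Noise-free density recursions with delayed feedback destabilise for
  large `r_m·lag`; generator and tests use growth rates inside the
  stability region so trajectories stay positive and bounded.

## Known limitations

* Only females are modelled; eggs are halved at creation.
* No spatial structure, hydrology or trap metadata; water enters only
  through the precipitation rules.
* Supplementary coefficient values not printed in the source literature
  (survival quadratics, blood-meal and egg-batch coefficients,
  density-dependence slopes, `A` coefficients) are stand-ins living in the
  species YAML files; analyses that depend on them are asserted as
  properties or with tolerance bands, never to printed precision.
* The diapause trigger is thermal only (no photoperiod), which makes the
  floodwater species' autumn egg bank sensitive to the threshold chosen
  (15 °C on the 10-day mean for *Ae. vexans*).
* ACF/PACF bands assume white noise; no ARMA order selection is attempted.
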