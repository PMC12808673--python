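# Methods

## The model and its assumptions

CBT is modelled as a first-order linear system driven by locomotor activity:

    ŷ_t = ŷ_{t−1} + a1·A_{t−1} + a2·(ŷ_{t−1} − T_min)

with Δt fixed at 1 min. The assumptions are: (i) activity heats with a
constant, state-independent gain `a1`; (ii) cooling is proportional to the
displacement from a constant steady state `T_min` with rate `−a2`;
(iii) parameters are stationary over the record; (iv) feeding, body mass and
ambient temperature are not modelled. Stability of long-horizon forecasts
requires `|1 + a2| < 1`, which is asserted on fitted parameters. The update
is affine, so the forecast has the closed form

    ŷ_t = T_min + (T_1 − T_min)·r^(t−1) + a1·Σ_{k<t} r^(t−2−k)·A_k,  r = 1 + a2,

implemented as a first-order IIR filter (`scipy.signal.lfilter`); a 14-day
forecast costs microseconds, which is what makes per-animal numerical
fitting cheap. The test suite checks the recursion against an independently
coded superposition oracle.

### Sign and intercept conventions

The dynamics are written with `+a2·(ŷ − T_min)` and `a2 < 0`. The
boundary-condition regressions report the equivalent single-variable form
`ΔT = a2·T + C` with `C = −a2·T_min`, i.e. the regression intercept maps
onto the steady state as `T_min = −C/slope`.

## Fitting

`fit()` minimises `J = Σ_t (y_t − ŷ_t)² + λ(a1² + a2²)` with L-BFGS-B under
bounds a1 ∈ [0, 1], a2 ∈ [−1, −1e−7], T_min ∈ [25, 42] °C, starting from
(a1 = 1e−3, a2 = −1e−2, T_min = 1st percentile of observed CBT). Choices:

* **λ = 1e−3 by default.** The penalty mainly guards against degenerate
  trade-offs between a1 and a2 on short or low-activity segments; at the
  fitted magnitudes (a1 ~ 1e−3, a2 ~ 1e−2) its contribution to J is
  negligible, so estimates are effectively least-squares.
* **T_min is not penalised.** It plays the role of an intercept; shrinking a
  temperature toward 0 °C has no physiological meaning.
* **Determinism.** A single bounded local search from a fixed start; the
  objective is smooth and, in practice, unimodal over the bounded box for
  telemetry-like inputs. Optional seeded multi-start (`n_starts`) exists for
  difficult data; non-convergence is reported via `converged=False`, never
  silently.
* **Day subsets fit as segments.** When a model is fit to a female's
  non-estrous or estrous days, each maximal run of consecutive selected days
  is forecast from its own first observed temperature and the squared errors
  are summed across segments — the only construction consistent with a
  forecast that may use just one observed value per contiguous stretch.

## Baselines

The lagged-linear (Weinert–Waterhouse-style) baseline regresses CBT on a
τ-minute rolling activity sum. The rolling window is **backward**
(`S_t = Σ_{k=t−τ+1..t} A_k`): the model is sometimes written with a forward
summation bound, but a "lag" that anticipates future activity is not causal,
so the backward window is used and the discrepancy documented here. τ is
selected in [1, 120] min by maximum Pearson correlation, ties toward the
smaller window, with a warning when even the best |r| < 0.1. The circadian
baseline is a linearised sine+cosine regression at a fixed 1440-min period
(the animals are entrained to LD 12:12; no free-running period estimation).

## Boundary-condition analysis

`ΔT_t = T_{t+1} − T_t` is paired with the *current* state `(T_t, A_t)` (the
difference direction is a convention; pairing the forward difference with
the current state is what makes the generative identity
`ΔT = a1·A + a2·(T − T_min)` exact on noiseless model data, which the tests
verify). All animals are pooled. The low-CBT threshold comparison defaults
to ≤ 35.25 °C and is configurable to strict <. The 2-D grid defaults to
0.25 °C × 2-count bins; empty cells are undefined (NaN), not zero.

## The synthetic cohort and its two noise regimes

The generator emulates the targeted study design: 13 males + 13 females,
14 days × 1440 min/day, lights on 06:00 / off 18:00, recording anchored at
lights-off. Activity is a per-minute two-state Markov chain
(bout-start probability 0.05/min in dark, 0.01/min in light, stop 0.04/min;
active minutes draw rounded gamma counts with mean 20), giving aperiodic,
dark-biased, nonnegative counts and a ~1 °C dark-phase temperature
elevation. Temperature follows the model dynamics; endogenous rhythms enter
the *dynamics* as per-minute sinusoid increments, so they survive into the
residuals of a subsequent fit rather than being absorbed as observation
error.

Sex-specific parameter distributions were fixed once at the population-level
coefficients the boundary analysis characterises: heating
a1 ~ N(0.0016, 0.0002) °C/count and cooling a2 ~ N(−0.0199, 0.0008)/min for
both sexes, steady states T_min ~ N(35.2, 0.15) °C (males) and
N(35.8, 0.15) °C (females) — males lower, pooled mean ≈ 35.5 °C so that the
pooled boundary intercept −a2·T̄ ≈ 0.70. Estrous is a block of 4 consecutive
days per female with a1 shifted by −0.0004 and a2 by −0.004 (both lower),
plus an optional 0.15 °C residual elevation 1–6 h post-lights-on; day 0 is
left unlabeled so a 14-day female record carries 9 labeled non-estrous and
4 estrous days.

Noise takes two routes, probing different statistical regimes:

* **Observation noise** (default, σ = 0.1 °C i.i.d. Gaussian on the observed
  trace): one-shot forecast residuals are white — Durbin–Watson ≈ 2, fit
  RMSE at the noise floor — which is the regime in which the residual and
  spectral machinery's type-I behaviour is meaningful.
* **Process noise** (white increments inside the dynamics,
  `boundary_regime_config()`, σ = 0.02 °C/min, no observation noise):
  the one-step difference `ΔT = a1·A + a2·(T − T_min) + η` is then exactly
  linear in the *observed* state, so pooled boundary OLS estimates the
  generative coefficients without attenuation. Observation noise, by
  contrast, biases a ΔT-on-T regression by ≈ −var(ε)/var(T) — comparable to
  a2 itself at realistic noise levels — so boundary characterisation on
  observation-noise data would measure the noise, not the dynamics.

The boundary-regime cohort is parameter-homogeneous at the pooled
coefficients (0.0016, −0.0199) with T_min = 35.25 °C: between-animal
parameter dispersion also attenuates a pooled slope, and placing the steady
state at the low-CBT threshold puts the below-threshold subset slightly
below steady state (mean ≈ −0.08 °C under the stationary process-noise
spread), which is what yields the small positive low-CBT intercept
(≈ +0.0014) that a threshold cutting *above* a resting distribution
produces. Real light-phase temperatures sit below the fitted steady state
for the same reason (endogenous circadian withdrawal), which the linear
generator cannot produce without attenuating the slope; the homogeneous
placement reproduces the geometry directly.

### What the generator does not emulate

Real telemetry features deliberately out of scope: quantised temperature
readouts, feeding-driven thermic effects, mass-dependent cooling, light-
seeking behaviour, infradian drift, non-Gaussian measurement error, and the
real dataset's exact activity-count distribution (only its qualitative
structure — aperiodicity, dark bias, nonnegativity — is matched). Passing
tests therefore demonstrate correctness of the estimators and the pipeline
under the model's own assumptions, not that the model is an adequate
description of any particular real dataset.

## Residuals and spectra

Median days are computed per mouse first (pointwise median over that
group's aligned days), then combined across mice by a second pointwise
median, so no animal dominates through extra days. Window sums use
half-open `[start, end)` hour windows from either anchor (lights-on is
minute 720 of the lights-off-anchored day). Both the 0–6 h and 1–6 h
post-lights-on windows are implemented, since both conventions appear in
practice for the estrous contrast.

Welch periodograms use 2880-sample (48 h) windows, 1440-sample (24 h)
overlap, per-window linear detrending and no taper beyond the detrend
(boxcar; a taper is available via the `window` argument). The white-noise
null permutes the pooled per-group residual samples — one permutation per
shuffle, 1000 shuffles, 95th percentile per frequency — then windows the
permuted series identically; the null series length is matched to a single
animal's series so window counts agree. Pooling across the group is the
default reading of a "population residual" shuffle; a per-mouse variant is
available by calling `shuffle_null` on a single animal's residuals. Band
verdicts ask whether the group-mean power exceeds the envelope anywhere in
the band (circadian: 20–28 h periods; ultradian: 1–12 h). Because the
group mean of 13 periodograms is compared against a single-periodogram
envelope, the test is conservative under the null.

## Group statistics

Kruskal–Wallis at α = 0.05 gates all-pairs Dunn tests (rank-sum z with tie
correction, written in-house as no installed package provides them) with
Benjamini–Hochberg adjustment. Male-vs-female contrasts use Mann–Whitney U;
non-estrous-vs-estrous uses the Wilcoxon signed-rank on within-animal pairs.
Paired Cohen's d is mean(Δ)/SD(Δ) with ddof = 1. "Separable by a simple
curve" is operationalised as quadratic discriminant analysis on
standardised (T_min, a1, a2) scored in-sample; 100% means a perfect
separating quadratic surface exists for the sample. Females contribute
their non-estrous fits by default (estrous fits can be included as extra
points).

## Problem sizes used by the automated checks

The reproduction script (`scripts/acceptance.py`) and the heavier tests use
scaled cohorts chosen to keep replicated Monte Carlo loops fast while
preserving each check's statistical structure: boundary CI coverage uses
50 cohorts of 2 animals × 4 days; residual-whiteness/type-I uses 5-animal ×
6-day groups (group-mean vs. envelope logic needs several animals);
injected-rhythm detection uses 3-animal × 6-day groups; RMSE ordering uses
single-animal 4-day records. Full-size (26 × 14-day) cohorts are used
wherever a single realisation suffices: the boundary coefficient
reproduction, model effect sizes, and sex separability.

## Known limitations

* Parameters are assumed stationary; slow drifts alias into residuals.
* The boundary regressions are only consistent estimators under
  dynamics-routed noise (see above); on real data they inherit whatever
  measurement noise the logger adds.
* The shuffle null models exchangeable (white) residuals; heavy-tailed but
  serially dependent residuals can exceed the envelope without any rhythm.
* In-sample separability with 26 points in 3-D is an existence statement
  about a separating surface, not a generalisation claim.
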