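# thermoact

State-space modelling of locomotor-activity (LA) heating and innate cooling
in mouse core-body-temperature (CBT) telemetry.

## The problem

Minute-resolution intraperitoneal telemetry gives paired CBT (°C) and LA
(activity counts/min) traces. Most of the visible structure in CBT is not
endogenous: activity heats the animal, and the body cools back toward a
steady state when activity stops. Because activity is itself strongly
day/night patterned, it injects power into both the circadian and ultradian
bands of any CBT periodogram, masking the rhythms a chronobiologist actually
wants to study (hormonal pulses, set-point oscillations, estrous effects).

`thermoact` fits a deliberately minimal, interpretable model of those two
deterministic processes, removes them, and asks what temporal structure is
left.

## The model

A 3-parameter linear difference equation at Δt = 1 min:

    ŷ_t = ŷ_{t−1} + a1·A_{t−1} + a2·(ŷ_{t−1} − T_min),     ŷ_1 = T_1

* `a1` (°C·count⁻¹·min⁻¹) — heating effect of activity,
* `a2` (min⁻¹, negative) — first-order cooling rate toward steady state,
* `T_min` (°C) — the steady-state/minimum temperature.

The forecast is purely recursive: a 14-day prediction (20,159 minutes beyond
the single observed starting temperature `T_1`) uses only the activity
trace. Parameters are fit per animal by bounded quasi-Newton minimisation of
the L2-regularised squared forecast error
`J = Σ(y_t − ŷ_t)² + λ(a1² + a2²)`.

Around the model the package provides:

* **Baselines** — the Weinert–Waterhouse lagged-linear fit
  (`ŷ_t = m·Σ_{k=t−τ+1..t} A_k + b`, with the lag window τ selected by
  maximum correlation) and a fixed-period circadian sine (cosinor) fit.
* **Boundary analysis** — pooled OLS of ΔT on CBT where LA = 0 and of ΔT on
  LA where CBT ≤ 35.25 °C, a degree-2 refit to probe curvature, and a binned
  2-D mean-ΔT map with negligible cells (|ΔT| < 0.0025 °C/min) tracing the
  heating/cooling nullcline.
* **Residual diagnostics** — lights-off-aligned 1440-minute median residual
  days per group (male / non-estrous / estrous), windowed residual sums,
  Durbin–Watson statistics.
* **Spectral null testing** — Welch periodograms (48 h windows, 24 h overlap,
  per-window linear detrend) of residuals against the 95th-percentile
  envelope of 1000 sample-shuffled periodograms, with circadian (20–28 h)
  and ultradian (1–12 h) band verdicts.
* **Group statistics** — Kruskal–Wallis + Dunn/Benjamini–Hochberg model
  comparisons, Mann–Whitney and paired Wilcoxon parameter contrasts,
  paired Cohen's d, and quadratic-discriminant sex separability in
  (T_min, a1, a2) space.
* **Synthetic telemetry** — a generator for full cohorts (13M + 13F × 14
  days by default) with a dark-biased Markov bout process for LA, the model
  dynamics for CBT, optional endogenous sinusoids, estrous parameter shifts,
  and a complete ground-truth ledger, so every stage is testable without any
  external data.

## Worked example

```python
from thermoact import SimulationConfig, make_cohort, fit
from thermoact.residuals import durbin_watson

records, truth = make_cohort(SimulationConfig(n_male=1, n_female=0, days=14, seed=42))
rec = records[0]
res = fit([(rec.cbt.values, rec.la.values)])
p = res.params
print(f"mouse {rec.mouse_id}: a1={p.a1:.5f} degC/count, a2={p.a2:.5f} /min, "
      f"T_min={p.t_min:.2f} degC, RMSE={res.rmse:.3f} degC")
print(f"residual Durbin-Watson: {durbin_watson(res.residuals.values):.2f}")
```

prints

```
mouse M01: a1=0.00169 degC/count, a2=-0.01951 /min, T_min=35.20 degC, RMSE=0.100 degC
residual Durbin-Watson: 2.01
```

The fit recovers this animal's generative parameters (a1 = 0.00168,
a2 = −0.01942, T_min = 35.20) to well under 1%, the RMSE sits at the 0.1 °C
observation-noise floor, and a Durbin–Watson of 2.01 says the residuals are
serially uncorrelated — the model removed all deterministic structure, as it
should on data it generated.

The same workflow is available from a shell:

```
thermoact simulate --seed 7 --out-dir run
thermoact fit      --telemetry run/telemetry.csv --labels run/labels.csv --out run/fits.json
thermoact spectra  --telemetry run/telemetry.csv --labels run/labels.csv --out-dir run/spectra
thermoact pipeline --seed 7 --out-dir run_all   # everything at once
```

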