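# Methods

## The measurement problem

Methods for measuring avian body temperature differ in invasiveness and
in where along the core–periphery gradient they sense. If a method is
stressful it can raise core temperature and metabolic rate; if it is
peripheral it can under-read, increasingly so in the cold. The pipeline
implements a cross-sectional comparison of four methods (intraperitoneal
and subcutaneous PIT tags; cloacal and cutaneous thermocouples) plus an
un-instrumented control, measured overnight in flow-through respirometry
chambers while the climate cabinet steps through 25, 5, −15, 5, 25 °C
(160 min per step, final step 80 min). A multiplexer gives each of five
birds one 10-min analyzer slot per 80-min cycle, bracketed by 15-min
baselines of animal-free air.

## Respirometry model

Gas rates use the steady-state mass balance for the analyzer chain
actually plumbed: RH meter → CO₂ analyzer → H₂O/CO₂ scrubbers → O₂
analyzer, with flow metered on the incurrent (dry, STPD) side. O₂
fractions are therefore on a dry CO₂-free basis, CO₂ fractions on a dry
basis after mathematical water scrubbing (F_dry = F_wet·BP/(BP−WVP), the
exact inverse of dilution). The closed forms (README) reduce to the
textbook FRi(FiO₂−FeO₂)/(1−FeO₂) when incurrent CO₂ is negligible; a
numerical mass-balance solver serves as an independent oracle in the
tests. Power uses the oxyjoule equivalent (16 + 5.164·RQ) J ml⁻¹ O₂;
RQ outside [0.7, 1.0] warns and is never clamped.

Baseline correction estimates the incurrent reference fractions at every
instant by linear interpolation between the means of the baseline
segments bracketing each bird sample. The first and last 60 s of each
baseline are trimmed as a washout guard (standard practice; the exact
trim is not critical because baselines are 15 min). Linear drift cancels
exactly under this bridge; only drift curvature between adjacent
baselines (~65 min apart) survives, which is why the generator's
sinusoidal drift component uses a 12 h period — its interpolation
residual (<1e−5 in fraction units) is below analyzer noise. No lag
correction is applied between analyzers (an optional shift parameter
exists but defaults to 0).

## Extraction rules

"Most stable 2 min" is operationalised as the contiguous 120-s window
minimising the sample SD of the metabolic-power series, stride 1 s,
earliest window on ties (the acquisition software's own definition is
proprietary; minimum SD is deterministic and oracle-checkable by
exhaustive search). The search runs on watts by default and is
configurable to V̇O₂. RMR per ambient temperature is the lowest window
mean across that temperature's cycles (25 °C has three cycles, 5 °C
four, −15 °C two). Body temperature is averaged over the closed window
interval; when no reading falls inside (e.g. thermocouple dropouts), the
single reading closest in time is used and flagged.

Because RMR is a minimum over noisy cycle means, it is biased slightly
downward, and more so where more cycles exist (about −2% at 5 °C with
four cycles versus −1% at −15 °C with two, given the ~2% per-cycle
plateau jitter). This inflates the −15 vs 5 °C marginal-mean ratio by
roughly +1–2 percentage points over the generated 53%. The pipeline
reports what the rule as stated produces; no debiasing is applied.

## Temperature processing

Calibration regresses chamber reference on raw reading (the direction
needed to map field readings to true temperature) and pools the bench
units per sensor kind — PIT versus thermocouple — which is what the
methods share hardware-wise; per-unit fits are available. Positive
slopes preserve ordering; slopes outside (0.8, 1.2) warn.

QC rules: a PIT value >45 °C is removed only when every other sample
within ±60 s is ≤42 °C, so isolated misreads go while sustained
(fever-like) plateaus stay; removed samples are flagged, never silently
dropped. The thermocouple recording window [30, 50] °C is inclusive.
Readings are rounded to the 0.1 °C tag resolution *before* 1-min
binning (bins anchored at integer minutes from recording start; empty
bins are missing). No interpolation or imputation is performed.

The consecutive disparity index uses the absolute value inside the sum,
D = Σ|ln(x_{t+1}/x_t)|/(n−1): without it the sum telescopes to
(ln xₙ − ln x₁)/(n−1), which cannot measure variability. Pairs spanning
a missing bin are skipped and the divisor reduced accordingly. D is
computed over the full night profile (baseline periods are not excised;
the bird wears its sensor continuously).

## Statistical models

Both responses (RMR in W; matched body temperature in °C) use linear
mixed models with method, ambient temperature (factor) and age as fixed
factors, body mass as a covariate, a random intercept per bird, and a
distinct residual SD per method (varIdent-style). The likelihood is
implemented directly: fixed effects are profiled out by GLS and the
optimizer runs over log variance components, with per-bird covariance
inverses in closed form (Sherman–Morrison), for both ML and REML.
statsmodels' MixedLM cannot fit groupwise residual variances, so it
serves as the independent oracle in the homoscedastic special case
rather than as the implementation.

The candidate set varies only the method × ambient and method × age
interactions (all main effects always retained). Candidates are fitted
by ML and compared by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), counting fixed
effects plus all variance components in k; the winner is refitted by
REML. A rank-deficient candidate (e.g. an empty method × age cell in a
small design) is flagged non-converged and excluded from selection.

Marginal means average over age with equal weights and fix mass at its
grand mean (standard reference-grid convention). Contrast inference uses
the normal approximation (z) rather than Kenward–Roger/Satterthwaite
degrees of freedom — a deliberate simplification; with ~65 birds the
difference is small. The Bonferroni family is the full contrast table
(all method pairs, within each ambient temperature when the interaction
is present). Wald χ² tests are Type-III-style block tests under
treatment coding. The random-intercept LRT refers 2Δℓ to χ²₁, which is
conservative for a boundary-tested variance.

Welch's ANOVA (weights nᵢ/sᵢ², Satterthwaite-type denominator df) and
Games–Howell (q = |Δx̄|/√(SE²/2) against the studentized range with
Welch–Satterthwaite df) are implemented from the standard formulas;
pingouin is the test-suite oracle. Balance checks (one-way ANOVA on each
mass variable; Pearson χ² on age × method and sex × method) go through
scipy with a guard returning F = 0, p = 1 for identical group means.

## Synthetic data: what it emulates, and what it does not

The generator produces, per night, one multiplexed 1 Hz analyzer stream
(excurrent O₂ CO₂-free/dry, CO₂ wet, water-vapour pressure, pressure,
flow, active channel) and per-bird temperature streams, with ground
truth retained for recovery testing. Its defaults encode the study
conditions; the key parameters:

| parameter | default | meaning |
|---|---|---|
| n_birds_per_method | 13 | nights; 5 birds (one per method) per night |
| flow_mean / flow_sd | 594 / 22 ml min⁻¹ | incurrent STPD dry flow |
| rmr_base_25 | 0.18 W | RMR at 17 g in thermoneutrality (free choice, plausible for a ~17 g nocturnal passerine; only ratios matter downstream) |
| rmr_ratio_5v25 / rmr_ratio_m15v5 | 1.29 / 1.53 | multiplicative cold response |
| mass_slope | 0.026 W g⁻¹ | additive mass effect |
| tb_core_25 / tb_drop_subTNZ | 38.0 / 1.5 °C | core level and sub-TNZ drop (free choices) |
| cu_deficit_5 / cu_deficit_m15 | 2.35 / 2.7 °C | cutaneous under-read below TNZ |
| wander_sd / wander_tau_s | 1.0 °C / 1800 s | slow within-night temperature wander, all methods |
| cl_jitter_sd / tau | 0.25 °C / 120 s | cloacal probe-movement jitter |
| misread_rate | 2e−5 | per-sample PIT spike probability (~matches the study's 41 in 2.3 M) |
| o2_noise_sd | 2e−5 | per-sample analyzer noise (fraction) |
| cycle_jitter_sd | 0.02 | relative SD of the per-cycle resting plateau |

Design choices worth noting:

* **Mass enters additively** (true RMR = rmr_base·ratio(T) +
  0.026·(m − 17) + bird intercept), matching the additive covariate in
  the inferential model; a multiplicative mass term would not be
  recoverable as a single W g⁻¹ coefficient. `mass_mean` parametrizes
  the mass at measurement; capture mass is derived from it.
* **Quiescent plateau**: each 10-min sample hides a flat 3-min plateau
  at the cycle's resting level, uniformly placed, with elevated and
  fluctuating activity metabolism elsewhere — so the stablest-window
  rule has a correct answer to find. Analyzer fractions are
  quasi-steady-state: chamber washout dynamics are deliberately not
  modelled (no "effective volume" correction exists downstream either).
* **Misreads** are single isolated spikes drawn on (46, 50] °C raw, with
  a minimum 130 s separation so each is unambiguously "single
  erratically occurring" — and stays >45 °C after any sane calibration.
* **Variability structure**: the CU CV excess (~1.7–1.9×) *emerges* from
  the configured deficits interacting with the chamber program on top of
  the shared 1.0 °C wander; `cu_noise_scale` is a dial left at 1. The CL
  disparity excess (~1.27×) comes from the probe jitter: with τ = 120 s
  and SD 0.25 °C the induced bin-to-bin disparity adds in quadrature to
  the wander's to give D(CL)/D(SC,IP) ≈ 1.27 analytically.
* Thermocouple streams drop out-of-window samples at source (a device
  setting); PIT streams quantize to 0.1 °C.

What the generator does **not** emulate: stress responses and their
dynamics, circadian drift beyond the chamber program, chamber washout
transients, analyzer lag, sensor failure/tag loss, and any
bird-to-night covariance beyond the random intercept. Passing recovery
tests therefore demonstrate that the pipeline's rules and models recover
the effects they were built for under realistic noise — not that the
generator reproduces every feature of live-bird recordings.

## Numerical choices

Stablest-window variance uses centered cumulative sums (stable for
near-constant segments) with variances rounded at 1e−15 before argmin so
exact ties break to the earliest start. LMM optimization runs
Nelder–Mead in log-SD space with a stationarity-checked restart;
variance parameters are kept within e^{±23} so degenerate zero-noise
fits stay representable. Contrasts with |estimate| below 1e−8 of the
coefficient scale are reported as z = 0 (p = 1) rather than 0/0.
Welch/Games–Howell refuse zero within-group variance; CV requires a
positive mean; D requires strictly positive values.

## Problem sizes

The default design (13 nights × 43 200 s of gas trace; 52 temperature
streams of 43 200 samples, ~2.2 M readings) analyses end to end in a few
seconds on one CPU. The recovery checks in the test suite and the
acceptance script average ten seeded replicates of this design, chosen
to keep seed-to-seed Monte-Carlo error on the headline percentages
around one percentage point.

## Known limitations

* Exact reproduction of the study's printed test statistics is
  impossible (the live-bird raw data are not deposited); only effect
  recovery on synthetic data is claimed.
* z-based contrast p-values are mildly anti-conservative at this sample
  size compared with Kenward–Roger.
* The min-over-cycles RMR definition carries the small cycle-count
  dependent downward bias described above; it is a property of the rule,
  not of the implementation.
* Calibration is linear only, matching the bench fixture's three
  reference points.
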