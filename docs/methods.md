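# Methods

## The calcium model

`caflux.model` implements a two-compartment description of intracellular
calcium in a cell on a conductive substrate.  The state is the pair of
concentrations ([Ca²⁺]ᵢ, [Ca²⁺]_ER), both in µM, and the dynamics are

    d[Ca²⁺]ᵢ/dt  = k·[Ca²⁺]_ER − k₁·[Ca²⁺]ᵢ + α·H([Ca²⁺]ᵢ)·[Ca²⁺]_ER + γ − β·[Ca²⁺]ᵢ
    d[Ca²⁺]_ER/dt = −(k·[Ca²⁺]_ER − k₁·[Ca²⁺]ᵢ + α·H([Ca²⁺]ᵢ)·[Ca²⁺]_ER)

with Hill activation H(c) = cⁿ/(δⁿ + cⁿ).  The terms are: passive ER leak
(k), SERCA uptake into the ER (k₁), calcium-induced calcium release through
the IP₃ receptor (α, half-occupation δ, Hill coefficient n), constant
plasma-membrane influx (γ) and linear efflux (β).  The ER is treated as a
concentration symmetric with the cytosol — no volume-ratio factor — exactly
as the equations above are written; no extension is added.

Default parameters (control condition): β = 2.0 s⁻¹, α = 1.3 s⁻¹,
γ = 2.0 µM s⁻¹, n = 4, δ = 1.3 µM, k = 0.01 s⁻¹, k₁ = 2.0 s⁻¹.

Two structural facts carry most of the analysis:

1. **Flux bookkeeping.**  The ER equation is the exact negative of the
   cytosol–ER exchange fluxes, so d([Ca²⁺]ᵢ + [Ca²⁺]_ER)/dt = γ − β·[Ca²⁺]ᵢ
   identically.
2. **Cycle-average law.**  Integrating (1) over one period of any limit
   cycle (or evaluating it at any steady state) forces the time-average of
   [Ca²⁺]ᵢ to equal γ/β.  Every simulated mean in this package can therefore
   be checked against a closed form, and the sweep/condition results are
   a verification of the integrator and period detection rather than
   unfalsifiable output.

The unique fixed point is ca_i\* = γ/β, ca_er\* = k₁·ca_i\*/(k + α·H(ca_i\*));
at the control parameters it is (1.0, 5.762) µM with Jacobian trace
+1.408 s⁻¹ — linearly unstable, so the model oscillates (a bounded
two-variable system with one repelling fixed point).  Disabling CICR
(α → 0) renders it stable.

### Conductivity conditions

Substrate electroconductivity enters through (β, γ).  A more conductive
extracellular environment shortens the membrane charging time, which is
modeled as faster influx and slower efflux.  The value triplet
{1.9, 2.0, 2.1} is assigned antagonistically:

| condition | γ (µM/s) | β (1/s) | mean [Ca²⁺]ᵢ = γ/β |
|-----------|----------|---------|---------------------|
| low       | 1.9      | 2.1     | 0.905 µM            |
| control   | 2.0      | 2.0     | 1.000 µM            |
| high      | 2.1      | 1.9     | 1.105 µM            |

The identical pairing (γ = β in every condition) would force the mean to
1 µM everywhere and make conductivity inert; the antagonistic pairing is
the only assignment under which mean cytosolic calcium rises with
conductivity, and it is recorded in all output metadata.

### Numerics

The default integrator is fixed-step classical RK4 with dt = 1 ms over
300 s (matching the 3-minute recording window), chosen for determinism in
tests; an adaptive option (scipy RK45, rtol 1e−9) is available.  The system
is not stiff at these parameter scales; RK4 self-convergence is verified at
4th order against a dt = 0.1 ms reference.  States are validated to remain
nonnegative (a drop below −1e−9 µM raises an integration error naming the
failing time, rather than clipping silently).  Cycle averages discard the
first 50% of the trajectory, delimit periods by upward crossings of the
post-transient mean, and average between the first and last crossing; a
post-transient peak-to-trough range below 1e−4 µM is classified "steady"
and averaged over the terminal plateau.  Initial conditions are unstated in
the source description; the default (0.1, 5.0) µM is configurable, and the
cycle-average law is verified from random positive starts (the attractor is
global in practice).

## Synthetic recordings

`caflux.synth` emulates 3-minute, 20 Hz, multi-cell Fluo-4 recordings.  In
parametric mode each cell is a pulse train: at each event time the signal
rises toward baseline + amplitude as 1 − exp(−t/τ_rise) for seven time
constants (so peaks are within 0.1% of the ceiling), then decays as
exp(−t/τ_decay).  Events start at half a period by default (event count =
⌊duration/period⌋) or at a random phase in cohort generation.  The
10–90% rise time of this kernel is ln(9)·τ_rise ≈ 2.197·τ_rise, and
likewise for decay — these are the ground-truth values recovery is tested
against.

Cohort defaults encode the emulated study conditions: 30 cells × 3
conditions, baseline 1.0, amplitude 2.0, period 30 s, τ_rise 1 s,
τ_decay 3 s, per-cell mean-1 lognormal jitter with CV 0.15 (lognormal keeps
parameters positive), Gaussian observation noise SD 0.2 (amplitude SNR 10
in the low condition), optional linear bleaching.  Condition effects follow
the reported phenotype directions — high conductivity raises amplitude
(×1.5 vs low), basal threshold (×1.3) and rise/decay times (×1.4) with
frequency unchanged (×1.0); the control condition sits at the geometric
midpoint.  The magnitudes are invented (the source reports the directions
graphically, not numerically) and configurable.  ODE mode replaces the
kernel with per-cell integrations of the calcium model at each condition's
(β, γ), jittered per cell and mapped to fluorescence by an affine gain.

Not emulated: focus drift, motion, ROI segmentation error, indicator
saturation.  Tests passing on these traces validate estimator correctness
under additive noise and bleaching, not robustness to every imaging
artifact.

## Trace featurization

`caflux.features` reduces each recording to the four comparison metrics
(mean transient amplitude, basal threshold, events/minute, 10–90% rise and
90–10% decay times).  No operational definitions exist in the source
imaging protocol, so the estimators are declared defaults, all exposed as
settings:

- **Baseline ("threshold")** — the 10th percentile of the raw signal.
  Exact when the trace spends at least that fraction of samples at rest;
  with tight periods or heavy noise it is biased upward/downward
  respectively (≈ −1.28σ under Gaussian noise), identically across
  conditions, so group contrasts are unaffected.
- **Noise** — MAD of first differences × 1.4826/√2 (differencing cancels
  the slow transient component).
- **Events** — local maxima of a 0.25 s moving-average copy of the trace,
  at least baseline + 3·noise_sd high, at least 2 s apart (closer peaks are
  merged keeping the higher, via the peak-finder's distance rule), and with
  prominence ≥ 3·noise_sd to reject threshold re-crossings on decay flanks.
  Event boundaries extend to where the smoothed signal falls below
  baseline + 1.5·noise_sd (hysteresis).
- **Kinetics** — linear-interpolated 10%→90% (rise) and 90%→10% (decay)
  crossing times around each peak.  Flanks truncated by a recording
  boundary are excluded from the rise/decay means but the events still
  count toward frequency, keeping kinetics unbiased.  Under noise the 10%
  crossing is absorbed into the noise floor, inflating rise/decay estimates
  additively — again identically across conditions.

Amplitude is peak minus baseline (not absolute peak), read from the
smoothed trace so the expected maximum of the noise over an excursion does
not inflate it.  Features are scale-equivariant (amplitude, threshold,
noise) or scale/shift-invariant (frequency, kinetics) and carry units as
metadata only.

## Group statistics

`caflux.stats` mirrors the study's decision procedure: per-group
Shapiro–Wilk at α = 0.05 gates one-way ANOVA + Tukey HSD; if any group
fails, the comparison falls back to Kruskal–Wallis with Dunn's rank post
hoc (Bonferroni), and the fallback is always flagged in the procedure log —
the source protocol specifies only the gate, not the failure branch.
"Distribution symmetry" is treated as covered by the Shapiro–Wilk gate; no
separate symmetry test is added.  Two-group contrasts use Student's t,
switching to Welch when the sample-variance ratio exceeds 4.  Features are
compared per metric with no cross-feature multiplicity correction
(matching per-metric reporting); a log note records this.  Statistics are
computed per cell; a grouping key can be supplied for future per-well
aggregation.  The comparative-Ct fold change is 2^−ΔΔCt with
ΔΔCt = (Ct_target − Ct_ref)_sample − (Ct_target − Ct_ref)_control.

Tukey adjusted p-values come from the studentized-range distribution;
tests cross-check q against explicit sum-of-squares formulas and p against
an independent library implementation.

### Calibration behavior

On null cohorts (all condition multipliers 1.0) the gated procedure
rejects at close to the nominal 5% per feature.  The basal-threshold
feature runs slightly hot (≈ 6% over thousands of null cohorts): its
per-cell distribution is a skewed lognormal-like mixture shaped by where
the 10th percentile lands relative to each cell's resting fraction, and the
normality gate's selection interacts mildly with the omnibus test.  This is
a property of the specified procedure on that feature, not an
implementation artifact — the unconditional ANOVA and Kruskal–Wallis levels
on the same feature are ≈ 4–5%.  A 500-cohort calibration estimate has a
binomial SE of ≈ 1%, so single batches scatter accordingly.

## Problem sizes

Defaults used by the test suite and the acceptance script: 300 s
trajectories at dt = 1 ms; cohorts of 3 × 30 cells at 20 Hz for 180 s;
500 null and 200 effect cohorts in the test-suite calibration (300/150 in
the acceptance script); 200 traces for noisy count accuracy; 50 noiseless
configurations for recovery.

## Known limitations

- Rise/decay estimates are additively inflated under observation noise
  (noise-floor absorption of the 10% crossing); orderings across conditions
  are preserved, and noiseless recovery is exact to the stated tolerances.
- The quantile baseline requires the period to exceed the full pulse span
  (≈ 7τ_rise + 4.6τ_decay) plus a resting stretch; denser spiking biases it
  upward.
- No spatial or stochastic calcium modeling, no IP₃ dynamics beyond the
  fixed δ, no mitochondrial pool, and no fitting of the model to imaging
  data.
- The ΔΔCt helper assumes amplification efficiency 2 exactly, as the
  comparative-Ct method does.
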