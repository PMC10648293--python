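# Methods

## Problem framing

During spine surgery, SSEPs are elicited by stimulating a peripheral nerve
(ulnar at 0.025–0.034 A, posterior tibial at 0.04–0.06 A) and recording
averaged trial waveforms from scalp electrode pairs (montages). The
end-tidal sevoflurane concentration *c* (vol%), charted once per minute by
the anesthesia information system, suppresses these waveforms
dose-dependently. Rather than regressing waveform metrics on *c*, the
pipeline uses *reverse regression*: *c* becomes the continuous output and
the waveform features the predictors. The quality of that inverse map —
holdout RMSE in vol% on patients never seen during any fitting step — is
the quantity of interest.

## Synthetic session generator

The generator emulates a ten-patient monitoring cohort without any real
recordings. Ages and sexes are reused from a published reference cohort
(mean age 58.8 y, population SD 7.7 y).

**Waveform model.** Each channel carries two named evoked components
(cortical ulnar: N20/P30; subcortical CS5–Fpz ulnar: N13/P14; tibial:
P37/N45), each a Gaussian bump with polarity `p` (N → −1, P → +1), base
amplitude `A0` (µV), base latency `L0` (ms) and width `w` (ms):

```
component(t; c) = p · A0 · exp(−k_A·c) · exp(−(t − (L0 + k_L·c))² / 2w²)
```

Defaults: N20 (2.0 µV, 20 ms, w 2.5), P30 (1.2, 30, 3.0), N13 (0.8, 13,
1.5), P14 (0.6, 14, 1.5), P37 (1.5, 37, 2.5), N45 (1.0, 45, 2.5);
`k_A = 0.3 /vol%`, `k_L = 1.0 ms/vol%`. The Gaussian shape was chosen for
its closed-form extremum (exact latency oracles) and smoothness; the
multiplicative-exponential amplitude law keeps amplitudes positive at any
dose, and the linear latency law is the simplest unbounded prolongation.
Widths are narrow enough that a neighbouring component's tail cannot move
the detected extremum off its nominal grid latency for the cortical-ulnar
and tibial pairs; the N13/P14 pair is only 1 ms apart, so its two bumps
overlap and the detected extrema sit about 1 ms off nominal (still inside
their search windows) — a known property, not a defect.

**Noise.** White Gaussian plus 1/f-shaped Gaussian noise, each with
SD 0.01 µV by default (0.5% of the largest component amplitude). The level
is deliberately small: per-sample noise accumulates over all ~500 samples
of a trial and therefore competes with the low-dimensional dose-driven
signal variance in PCA. At 0.01 µV the first three principal components of
a per-channel trial matrix retain ≈ 97–99% of variance (median ≈ 98% over
20 seeds), satisfying the design requirement of ≥ 95%; at ten times this
level they retain well under half.

**Concentration profile.** Piecewise per-minute series over a 120-minute
session: linear induction ramp (10 min) from 0 to the maintenance mean
(2.0 vol%), an AR(1) maintenance fluctuation (stationary SD 0.25, lag-1
correlation 0.9 — slow drift rather than white jitter), and an exponential
emergence decay (last 15 min, rate 0.25/min), clipped at zero. Variability
is concentrated at the start and end of the session, as in real cases.
The ramp and decay are parameterized by duration + rate; setting both
durations and the maintenance SD to zero yields a constant profile.

**Timing.** Each nerve's stimulation events sit on an even grid over
[120 s, end − 120 s] with ±30% uniform jitter; a nerve's three montages
share the event timestamp, so downstream rows are dense per nerve. The
waveform is driven by the charted series linearly interpolated to the
stimulation time; synchronization downstream re-matches to the *nearest
reading*, introducing a realistic sub-minute discretization error.

**Determinism.** All randomness descends from `GeneratorConfig.seed`
(profiles from `(seed, patient_index)`, waveforms from
`(seed, 1000003, patient_index)`), so identical configs reproduce
bit-identical cohorts. Trials-per-case counts and acquisition cadence are
not publicly reported quantities; the defaults (30 trials/nerve) are
configurable choices, not inferences.

## Session model and synchronization

Sessions are stored in a self-documented JSON dialect (schema_version,
patient block, channels array of trial arrays) and a two-column anesthesia
CSV; the proprietary vendor export format is out of scope. Validation
errors name the offending field path. Trials are matched to the
nearest-in-time concentration reading within a tolerance (default 60 s);
exact midpoints go to the earlier reading; unmatched trials are excluded
and counted. Nearest-match was chosen over linear interpolation because
charted readings are themselves the ground truth at one-minute resolution;
every matched concentration appears verbatim in the series.

## Feature extraction

* **Evoked latency/amplitude** — strict argmax (positive component) and
  argmin (negative component) within per-component search windows (N20
  15–25 ms, P30 25–40, N13 10–16, P14 11–18, P37 30–45, N45 40–55); ties
  break to the earlier sample. Windows are config-exposed; only the
  nominal component latencies are fixed by nomenclature.
* **Phase-space curve area** — 3-dimensional time-delay embedding
  `[x(t), x(t+τ), x(t+2τ)]` with τ = 2 ms, projected onto its first two
  coordinates; the feature is the absolute shoelace area of the closed
  projected polygon. A trajectory winding a loop k times reports k·(loop
  area); a quarter-period delay on a one-period sinusoid of amplitude A
  gives πA², the closed form used as an oracle. The embedding is built
  *within* one trial; a cross-trial variant (connecting trial points) is a
  conceivable alternative reading and was deliberately not implemented.
* **Time-frequency peak** — Hann-windowed magnitude-squared spectrogram
  (20 ms window, 50% overlap), global maximum within 10–500 Hz; returns
  (frequency, power, time-bin center). An all-zero trial returns the
  documented degenerate triple (band minimum, 0, 0) with a warning.
* **PCA scores** — fitted per patient × channel across that patient's
  synchronized trials (mean-centered, full SVD, top 3 components, sign
  fixed so each component's largest-magnitude loading is positive).
  Per-patient scope was chosen over pooled-cohort PCA so that no test
  patient's waveforms can influence training-feature construction.

## Normalization and selection

Quartiles use linear interpolation between order statistics. Zero-IQR
(constant) features are flagged and dropped — in synthetic data this
regularly removes e.g. a channel's `tfa_peak_freq` when the dominant
frequency bin never changes. The target is *not* normalized: keeping *c*
in vol% makes RMSEs physically interpretable, and the automatic SVM
constants (below) adapt to the response scale instead.

MRMR uses plug-in mutual information on equal-frequency bins
(`bins = min(10, ⌈√n⌉)`), greedy quotient scheme: first pick by relevance
MI(f; y), later picks by relevance ÷ (mean MI with selected + 10⁻¹²).
Features with relevance ≤ 0 (after binning this means constant features)
are "insignificant" and never selected, so a nerve can legitimately yield
fewer than k features; the threshold is config-exposed. The estimator and
the greedy loop are both verified against independent brute-force oracles.

## Model bank

All presets share one `train(spec, X, y, seed) → model` / `predict`
contract and are deterministic under a fixed seed.

| preset | key parameters | default source |
|---|---|---|
| linear | OLS | — |
| fine/medium/coarse tree | min leaf 4/12/36, min parent 2× leaf, MSE splits | coarse leaf = 36 is the documented value; 4/12 follow the common preset ladder |
| linear/quadratic/cubic SVM | poly kernel degree 1/2/3, standardized inputs, C = IQR(y)/1.349, ε = IQR(y)/13.49, kernel scale = median pairwise distance | for a unit-IQR response the constants evaluate to 0.7413 and 0.0741 |
| narrow/medium/wide net | one ReLU hidden layer 10/25/100, L-BFGS, ≤1000 iterations | widths follow the narrow/medium/wide ladder |

1.349 is the IQR of the standard normal, so C tracks a robust estimate of
the response SD. The "auto" kernel scale heuristic (median pairwise
Euclidean distance among standardized predictors, deterministically
thinned above 500 rows) is one reasonable reading of an undocumented
convention; it is exposed as a hyperparameter. `max_splits` defaults to
unlimited because any printed split count is data-size dependent.

## Evaluation protocol

Two patients (of ten; configurable) are held out before any fitting:
normalization statistics, MRMR ranking, and model weights see training
patients only (a `fit_normalizer_on_all` switch reproduces the
consolidated-cohort alternative; leakage-safe is the default, and a test
corrupts held-out rows to prove nothing fitted moves). Cross-validation is
5-fold at the trial level within the training patients — fold metrics are
pooled over out-of-fold predictions, so R² may be negative — with an
optional patient-grouped variant. The tournament picks the lowest pooled
validation RMSE (ties resolve to the earlier preset in the canonical
listing order) and scores *only the winner* on the held-out patients.

## What the synthetic benchmark does and does not show

The generator produces an idealized dose response: exact exponential
amplitude decay, linear latency shift, stationary Gaussian/1-f noise, no
surgical events, positioning artifacts, electrode impedance drift,
hemodynamic covariates, or inter-patient variation in component morphology
beyond the seeded noise. Passing the recovery suite therefore shows the
*pipeline machinery* is correct and leak-free — not that real
intraoperative data would be this predictable; holdout RMSEs on synthetic
cohorts (≈ 0.07 vol% for the winner at default settings) are far below
what heterogeneous clinical recordings yield. The replicate recovery
check uses reduced problem sizes (5 patients × 12 trials/nerve at 2 kHz
across 20 seeded cohorts) — ample to separate signal recovery from the
constant-predictor baseline.

## Numerical conventions and degenerate inputs

Ties in extremum detection → earlier sample; synchronization midpoint ties
→ earlier reading; MRMR score ties → earlier column. Constant targets
train fine and predict the constant; SVR falls back to C = 1, ε = 0.1 when
IQR(y) = 0. Zero-variance PCA inputs return zero scores and an undefined
(NaN) variance fraction with a warning. All file formats are plain text
(JSON/CSV); sessions round-trip exactly at float precision.
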