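# ssepml

Quantifying and predicting the effect of the volatile anesthetic
**sevoflurane** on **somatosensory evoked potentials (SSEPs)** recorded
during spine surgery.

Volatile anesthetics attenuate the amplitude and prolong the latency of
SSEP components in a dose-dependent way, which complicates the
interpretation of intraoperative neuromonitoring (IONM) alarms. `ssepml`
is a library for researchers who want to study that relationship
quantitatively: it turns raw per-trial SSEP waveforms plus the
anesthesia chart into a feature table, and then asks — via *reverse
regression* — how well the end-tidal sevoflurane concentration *c* (vol%)
can be predicted back from the waveform features alone.

Because real intraoperative recordings are rarely shareable, the package
ships a first-class synthetic session generator with a known, closed-form
dose effect: each evoked component is a Gaussian bump

```
x(t) = Σ_j  p_j · A_j · exp(−k_A·c) · exp(−(t − (L_j + k_L·c))² / 2w_j²) + noise
```

so amplitudes shrink by `exp(−k_A·c)` and latencies shift by `k_L·c` ms —
the direction reported for sevoflurane — and every downstream stage can be
tested against ground truth.

## Pipeline

1. **Sessions** (`ssepml.session`, `ssepml.synth`) — 10 patients, 4
   monitored nerves (left/right ulnar, left/right posterior tibial), 3
   recording montages per nerve (e.g. CP4–Fpz, CP4–CP3, CS5–Fpz for the
   left ulnar), per-minute end-tidal sevoflurane readings; trials are
   matched to the nearest-in-time reading.
2. **Features** (`ssepml.features`) — 11 per channel: phase-space-curve
   area, evoked latency peak/valley (P30/N20, P14/N13, P37/N45), evoked
   amplitude peak/valley, spectrogram peak frequency/power/time, and
   scores on the channel's first three principal components. 3 channels ×
   11 = 33 per nerve; 4 nerves × 33 = 132 per patient.
3. **Preparation** (`ssepml.prep`) — robust IQR normalization
   `x' = (x − median)/(Q3 − Q1)`, fitted on training patients only;
   concentration framed as the regression target, kept in vol%.
4. **Selection** (`ssepml.mrmr`) — greedy quotient MRMR
   (relevance ÷ mean redundancy, plug-in mutual information on
   equal-frequency bins); top ten features per nerve.
5. **Models** (`ssepml.models`) — ten presets under one train/predict
   contract: linear; fine/medium/coarse regression trees (min leaf
   4/12/36); linear/quadratic/cubic ε-insensitive SVMs with automatic
   `C = IQR(y)/1.349`, `ε = IQR(y)/13.49`; narrow/medium/wide (10/25/100
   unit) neural networks.
6. **Evaluation** (`ssepml.evaluation`) — 5-fold cross-validation on 8
   training patients, winner by validation RMSE, single holdout score on
   the 2 untouched test patients.

## Worked example

`examples/04_model_tournament.py` simulates a five-patient cohort, holds
one patient out, and runs the full tournament on the left ulnar nerve:

```
selected features: 10
               rmse_validation  r2_validation  mse_validation  mae_validation  rmse_test
linear                  0.0659         0.9914          0.0043          0.0518     0.0668
fine_tree               0.1715         0.9420          0.0294          0.1151        NaN
...
coarse_tree             0.7430        -0.0894          0.5520          0.5778        NaN

winner: linear
holdout RMSE on patient P05: 0.0668 vol%
constant-predictor baseline (sd of test concentrations): 0.7086 vol%
```

The winner's holdout RMSE (0.067 vol%) is an order of magnitude below the
constant-predictor baseline (0.709 vol%): the models recover the
anesthetic concentration of an *unseen* patient from waveform features
alone. Only the winning preset is ever scored on the held-out patient.
The other examples (`01`–`03`) walk through simulation, feature
extraction, and MRMR ranking individually.

A thin CLI mirrors the stages:

```
ssepml simulate --seed 0 --n-patients 10 --out-dir runs/sessions
ssepml features --sessions-dir runs/sessions --out runs/features.csv
ssepml select   --features runs/features.csv --nerve left_ulnar --k 10 --out-json runs/rank.json
ssepml evaluate --features runs/features.csv --nerve left_ulnar --out runs/report.json
ssepml run-all  --config config.yaml --out-dir runs/full
```

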