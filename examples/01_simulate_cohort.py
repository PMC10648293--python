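"""Simulate a synthetic SSEP cohort and inspect its structure.

Generates three patient sessions — four monitored nerves x three recording
montages x stimulation-locked trials, plus a per-minute end-tidal
sevoflurane series — and prints what a session contains.
"""

import numpy as np

from ssepml import GeneratorConfig, generate_cohort

cfg = GeneratorConfig(n_patients=3, trials_per_nerve=10, seed=42)
cohort = generate_cohort(cfg)

for session in cohort:
    channels = {(t.nerve, t.montage) for t in session.trials}
    c = session.anesthesia.et_sevo
    print(
        f"{session.patient_id} (age {session.age}, {session.sex}): "
        f"{len(session.trials)} trials over {len(channels)} channels, "
        f"sevoflurane {c.min():.2f}-{c.max():.2f} vol% "
        f"({len(c)} one-per-minute readings)"
    )

session = cohort[0]
trial = session.channel_trials("left_ulnar", "CP4-Fpz")[0]
print(
    f"\nfirst left-ulnar CP4-Fpz trial: {trial.samples.size} samples at "
    f"{trial.sample_rate:.0f} Hz ({trial.window_ms:.0f} ms post-stimulus), "
    f"stimulated at t={trial.timestamp:.0f} s"
)
print(
    "waveform extremes: "
    f"min {trial.samples.min():.2f} uV at {trial.times_ms[np.argmin(trial.samples)]:.1f} ms (N20), "
    f"max {trial.samples.max():.2f} uV at {trial.times_ms[np.argmax(trial.samples)]:.1f} ms (P30)"
)
# The minimum near 20 ms and maximum near 30 ms are the cortical ulnar
# components; higher anesthetic concentration shrinks and delays them.
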