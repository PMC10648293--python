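"""Extract the 11-per-channel feature table from a synthetic patient.

Each synchronized stimulation event of a nerve becomes one row carrying the
nerve's 33 features (3 channels x 11 features); the full column universe
across four nerves is 132. The final column is the matched end-tidal
sevoflurane concentration — the regression target.
"""

from ssepml import GeneratorConfig, assemble_feature_table, generate_patient

patient = generate_patient(GeneratorConfig(seed=7, trials_per_nerve=10), 0)
table = assemble_feature_table(patient)

feature_cols = [c for c in table.columns if "." in c]
print(f"rows (synced events): {len(table)}")
print(f"feature columns: {len(feature_cols)} (11 per channel x 12 channels)")

row = table[table["nerve"] == "left_ulnar"].iloc[0]
print(f"\none left-ulnar event at t={row['timestamp_s']:.0f} s, "
      f"et_sevo={row['et_sevo_pct']:.2f} vol%:")
for name in ("lat_valley", "lat_peak", "amp_valley", "amp_peak", "psc_area", "tfa_peak_freq"):
    col = f"left_ulnar.CP4-Fpz.{name}"
    print(f"  {col:38s} = {row[col]:10.4f}")
# lat_valley/lat_peak are the N20/P30 latencies (ms); amplitudes are in uV;
# psc_area is the delay-embedded phase-curve area; tfa_peak_freq the
# dominant spectrogram frequency (Hz).
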