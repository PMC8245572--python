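"""Simulate a labelled accelerometer trace and summarise it into epochs.

Builds five minutes of synthetic cat accelerometry (12 behaviours,
50 Hz), segments it into 1-s epochs and prints the per-behaviour epoch
counts plus one feature row. Each row is one second of data described
by 26 summary variables.
"""

import somtag as st

dataset = st.simulate_trace(st.default_behaviour_library(), total_s=300, seed=1)
table = st.build_feature_table(dataset.trace, dataset.intervals)

print(f"trace: {len(dataset.trace)} samples at {dataset.trace.rate_hz:.0f} Hz, "
      f"{len(dataset.intervals)} bouts -> {len(table)} epochs")
print("\nepochs per behaviour:")
print(table["behaviour"].value_counts().to_string())
print("\nfirst epoch's features (g / unitless):")
print(table.iloc[0][st.feature_columns(table)].astype(float).round(4).to_string())
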