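"""Train a 7x7 supervised SOM and score it on held-out epochs.

Uses the default synthetic benchmark: a 2,000-epoch training draw from
the bib_off pool, evaluated on an independent bib_off test trace. The
printed per-class table shows sensitivity (recall), precision,
specificity and per-class accuracy; overall accuracy is the fraction of
all test epochs classified correctly.
"""

import numpy as np

import somtag as st

bench = st.make_benchmark(seed=1)
rng = np.random.default_rng(0)
idx = rng.choice(len(bench.train_off), 2000, replace=True)

model = st.train_supersom(bench.train_off.iloc[idx], st.make_grid(7, 7), seed=0)
m = st.evaluate_model(model, bench.test_off)

print(f"held-out epochs: {len(bench.test_off)}")
print(f"overall accuracy: {m.overall_accuracy:.4f}")
cols = ["sensitivity", "precision", "specificity", "accuracy"]
print(m.per_class[cols].round(3).to_string())

rf = st.rf_baseline(bench.train_off.iloc[idx], bench.test_off, seed=0)
print(f"\nrandom-forest baseline (100 trees, mtry 4): {rf.overall_accuracy:.4f}")
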