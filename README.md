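# somtag

Behaviour classification from animal-borne tri-axial accelerometers
with supervised Kohonen super self-organising maps (super-SOMs), plus a
bootstrap procedure that detects behaviour-specific biomechanical
change between two treatments.

## Who this is for

Movement ecologists and biologgers who annotate accelerometer traces
against video, want an interpretable classifier for a fine-scale
ethogram (here: 12 domestic-cat behaviours in three groups — sedentary,
eating/locomotive, hunting), and need to ask not just *"what is the
animal doing?"* but *"did an intervention change how it does it?"* —
for example, whether a prey-protector bib alters a cat's gait.

## The method

1. **Clock sync** — calibration taps (bursts of raps on the device,
   visible on video and as spikes where `|‖a‖ − 1 g|` exceeds a
   threshold) anchor a linear clock model
   `device = reference + offset + drift·t`, fitted by least squares;
   video label intervals are mapped onto device time.
2. **Epochs & features** — labelled spans are cut into 1-s windows
   (50 samples at 50 Hz), labelled by majority; each epoch is
   summarised by 26 variables: per-axis mean/min/max/SD, SMA, max and
   sum of ODBA (Σ|dᵢ|) and VDBA (‖d‖) on gravity-free samples, axis
   correlations, skewness and kurtosis.
3. **Super-SOM** — a hexagonal grid (default 7×7) trained online on two
   layers at once, the scaled features and a one-hot class layer; the
   best-matching unit minimises the layer-weighted distance, codebooks
   update by `w ← w + α·h·(x − w)` with a linearly declining learning
   rate and neighbourhood radius. Prediction finds the BMU from
   features alone and reads the class off the activity codebook. The
   map and its component planes make the classifier inspectable.
4. **Evaluation** — per-class sensitivity, precision, specificity and
   accuracy from the confusion matrix; training-size and grid-size
   sensitivity sweeps; a random-forest baseline (100 trees, mtry 4).
5. **Treatment comparison** — the classifier is retrained on bootstrap
   draws from the reference condition and scored per behaviour on both
   conditions; medians with 2.5–97.5 percentile CIs give per-behaviour
   verdicts: disjoint CIs → *significant*, median-inside-CI →
   *no_difference*, else *equivocal*.

A seeded synthetic ethogram simulator (harmonics + bursts + noise per
behaviour, exponential bouts, injectable treatment effects, embedded
calibration taps) exercises the entire pipeline without any field data.

## Worked example

```python
import numpy as np
import somtag as st

bench = st.make_benchmark(seed=1)                      # synthetic study
idx = np.random.default_rng(0).choice(len(bench.train_off), 2000, replace=True)
model = st.train_supersom(bench.train_off.iloc[idx], st.make_grid(7, 7), seed=0)
m = st.evaluate_model(model, bench.test_off)
print(round(m.overall_accuracy, 4))
```

prints `0.9643` — the fraction of ~3,000 held-out 1-s epochs whose
behaviour the 49-unit map classifies correctly. The treatment test:

```python
comp = st.bootstrap_compare(bench.train_off, bench.test_off, bench.test_on,
                            train_n=2000, n_boot=100, seed=0)
print(comp.verdicts["walking"], comp.verdicts["lying"])
```

prints `significant no_difference`: the synthetic bib perturbs walking
(amplitude ×1.3, slower cadence, looser limb phasing), so its
predictability collapses onto the trotting signature (bib_off median
per-class accuracy 0.996 vs bib_on 0.935, disjoint CIs), while the
untouched sedentary postures are indistinguishable between conditions.

More narrative scripts live in `examples/` (simulation & features,
clock calibration, training & evaluation, the bib comparison,
sensitivity sweeps, maps & component planes). A thin CLI mirrors the
library:

```bash
somtag simulate --duration 3600 --seed 1 --out-trace t.csv --out-labels l.csv
somtag extract --trace t.csv --labels l.csv --out f.csv
somtag train --features f.csv --grid 7x7 --seed 1 --out model.json
somtag run --out-dir runs/demo            # full pipeline + figures
```

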