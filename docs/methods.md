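# Methods

## Problem and scope

`somtag` classifies fine-scale animal behaviours from body-mounted
tri-axial accelerometers and tests whether an experimental treatment
(here: a prey-protector bib fitted to domestic cats) alters the
biomechanics of specific behaviours. The pipeline is: clock
synchronisation of device and video annotations → 1-s epoch
segmentation with majority labels → 26-variable feature summarisation →
supervised Kohonen super self-organising map (super-SOM) classification
→ confusion-matrix metrics, sensitivity sweeps and a bootstrap
percentile-CI treatment comparison. A synthetic ethogram simulator
generates fully labelled data so every stage is testable without any
field recordings.

## Clock model and tap calibration

Logger clocks drift on the order of 0.18 s/h relative to the video
reference. Calibration taps (bursts of five raps on the device) are
detected as samples whose acceleration-vector norm deviates from 1 g by
more than a threshold (default 3 g), merged into bursts by a refractory
gap (default 0.5 s); a burst with at least `min_spikes` (default 3)
candidate samples is an event timed at its first spike. Using the norm
deviation makes detection orientation-free. Device-vs-reference tap
pairs are fitted with a linear clock model, `device = reference +
offset + drift·t`, by ordinary least squares on the differences; all
pairs (including mid-deployment taps) are weighted equally. Fits with
|drift| above a configurable bound (default 5 s/h) are rejected as
mispaired. Higher-order drift is deliberately not modelled: the
manufacturer specification is a constant rate.

## Epochs and features

Time is seconds as floats; intervals are half-open `[start, end)` when
mapped to samples. Within every maximal contiguous labelled span,
consecutive non-overlapping windows of `round(rate × 1 s)` samples (50
at 50 Hz) are cut from the span's first sample; trailing partial
windows are dropped. Each window's label is the behaviour with the
maximum sample frequency inside it; ties go to the behaviour occurring
first in the window. The stride is a knob (`stride_s`) for users who
want true sliding windows; the default of one epoch per second matches
the common counting convention (n epochs ≈ n labelled seconds).

The default `galea26` profile computes exactly 26 features per epoch:
per-axis mean/min/max/SD on raw samples (12), SMA (1), max and sum of
per-sample ODBA (2) and VDBA (2), Pearson correlations XY/YZ/XZ (3),
and per-axis skewness and excess kurtosis (6). Skewness is
Fisher–Pearson g1 and kurtosis is excess g2, both with the biased N
denominator; SDs likewise use the N denominator. Zero-variance axes
yield correlation/skewness/kurtosis of 0 by convention. The
`galea_full` profile re-adds min-ODBA and min-VDBA (28 features); a raw
"axial acceleration" triple is not included because it has no
epoch-level summary meaning distinct from the mean. The dynamic
(gravity-free) component subtracts a centred running mean of each axis
(default window 2 s, standard in the dynamic-body-acceleration
literature; truncated at the trace edges; for even windows the extra
sample sits left of centre). SMA is computed on dynamic samples,
matching its use as an activity measure; a raw-sample variant is a
configuration away.

## Supervised super-SOM

Two layers share one hexagonal unit grid (default 7×7 = 49 units, rows
offset by 0.5 with spacing √3/2 so nearest neighbours are at distance
1): the *measurements* layer holds the standardised feature vectors and
the *activity* layer a one-hot encoding of the 12 classes. Features are
standardised by training mean/SD (constant features are flagged and
excluded from distances); the class layer is left as indicators.
Per-layer squared Euclidean distances are divided by a data-estimated
mean squared pair distance (from a seeded subsample of ≤100 rows) so
layers of different dimensionality contribute comparably; user weights
(default 1, 1) multiply on top.

Training is classic online competitive learning: codebooks are
initialised from a seeded sample of training rows; for `rlen` (default
100) full presentations in seeded random order, the best-matching unit
minimises the layer-weighted distance, and both codebooks update as
`w ← w + α·h·(x − w)`. The learning rate α declines linearly (default
0.05 → 0.01) over all steps; the neighbourhood h is a bubble kernel
(1 within the radius, else 0; Gaussian optional) whose radius declines
linearly from the 2/3 quantile of inter-unit distances to 0. All ties
(BMU, class argmax) break to the lowest index, so identical (data,
parameters, seed) give bit-identical models. These defaults
reconstruct the reference super-SOM implementation's documented
behaviour; every one of them is configurable. The training loop is
compiled with numba for speed; with the radius forced to 0, a constant
α and the class layer weighted out it reduces exactly to online vector
quantisation, which the test suite exploits as an independent oracle.

Prediction scales incoming rows with the stored training scaling, finds
the BMU on the measurements layer only, and returns the argmax of the
BMU's activity codebook. Codebook distances for map clustering use the
same layer weighting as the BMU search; hierarchical clustering is
complete linkage (the reference clustering routine's default), cut to k
clusters and relabelled in order of first unit appearance. Component
planes are codebook columns de-standardised to original units.

## Evaluation

Confusion matrices have predicted classes on rows and observed classes
on columns. Per-class one-vs-rest metrics are sensitivity TP/(TP+FN),
precision TP/(TP+FP), specificity TN/(TN+FP) and accuracy
(TP+TN)/total; zero denominators yield NaN ("undefined"), which macro
averages and bootstrap summaries exclude rather than impute. Sweeps
draw training subsets *with replacement* (as is conventional for this
design, even for sizes exceeding the pool) and test on the undrawn
rows; the grid sweep enumerates the full Cartesian product of side
lengths (4–9 → 36 configurations).

The bootstrap treatment comparison retrains the classifier on each of
`n_boot` resampled training draws from the reference-condition pool and
scores the per-behaviour metric on both test conditions with every
replicate. Summaries are the median and the 2.5/97.5 percentile
interval (linear interpolation between order statistics). Verdicts per
behaviour: disjoint CIs → *significant*; either median inside the other
CI → *no_difference*; otherwise *equivocal*. The per-behaviour metric
defaults to per-class accuracy — the comparison's y-axis is not pinned
down by convention — and can be switched to sensitivity. The random
forest baseline (100 trees, 4 candidate variables per split) is the one
off-the-shelf model call; it is the comparator, not the contribution.

## Synthetic ethogram generator

Each behaviour is generated from a harmonic + burst + noise family:
1 g along a fixed postural orientation, per-axis sinusoids at a gait
frequency with fixed inter-axis phase offsets, optional Gaussian burst
pulses, optional per-sample phase jitter, and white noise, clipped to
the logger's ±8 g range. This family is chosen because the in-scope
features respond to exactly these degrees of freedom: orientation →
means; amplitude → SDs, ODBA/VDBA, SMA; bursts → maxima; phase
offsets/jitter → correlations. No biomechanical realism is claimed: in
particular, real gait frequency content, inter-individual variability,
and transitions between behaviours are not modelled, so passing tests
demonstrate the correctness and sensitivity of the *method*, not field
performance on real cats.

Default parameter table (orientation as unit vector; amplitudes in g;
frequency in Hz; bouts in s):

| behaviour | group | orientation | freq | amplitudes | bursts (rate, peak, width) | noise | bout | weight |
|---|---|---|---|---|---|---|---|---|
| lying | sedentary | (0, .70, .71) | – | – | – | .020 | 40 | 1.0 |
| sitting | sedentary | (.35, 0, .94) | – | – | – | .020 | 30 | 1.0 |
| grooming | sedentary | (.10, .30, .95) | 1.5 | (.06, .10, .06) | – | .030 | 20 | 0.9 |
| watching | sedentary | (−.30, .05, .95) | – | – | – | .025 | 30 | 1.0 |
| eating_drinking | eat/loco | (.55, 0, .84) | 2.2 | (.14, .07, .18) | – | .030 | 20 | 1.2 |
| walking | eat/loco | (.05, 0, 1) | 1.8 | (.32, .20, .42) | – | .040 | 15 | 1.2 |
| trotting | eat/loco | (.08, 0, 1) | 3.2 | (.416, .26, .546) | – | .050 | 10 | 0.8 |
| galloping | hunting | (.12, 0, 1) | 4.2 | (1.30, .55, 1.60) | – | .080 | 6 | 0.25 |
| jumping | hunting | (0, 0, 1) | – | – | (1.2/s, 4.5 g, .12 s) | .050 | 5 | 0.30 |
| pouncing | hunting | (.45, 0, .89) | 2.5 | (.15, .10, .20) | (0.8/s, 2.8 g, .20 s) | .050 | 5 | 0.30 |
| swatting | hunting | (.20, .12, .97) | 5.0 | (.10, .50, .12) | – | .040 | 8 | 0.40 |
| biting_holding | hunting | (.52, .08, .85) | 8.0 | (.182, .091, .234) | – | .035 | 10 | 0.45 |

Hunting behaviours carry deliberately low selection weights so they are
scarce, qualitatively mirroring real deployments where galloping and
pouncing are rare. Two deliberate design couplings give the treatment
effect a *recoverable* planted truth: trotting sits exactly one
amplitude step (×1.3) above walking with identical limb phasing, and
biting/holding is an eating-like posture at ×1.3 eating amplitude with
intrinsic phase jitter (0.8 rad) that halves its axis correlations.
The default treatment effect multiplies amplitudes by 1.3 and the gait
frequency by 0.85 and adds 0.8 rad phase jitter for the affected set
{walking, eating_drinking}. The jitter value follows from signal
theory: per-axis jitter with sd s multiplies inter-axis harmonic
correlations by exp(−s²), so 0.8 rad roughly halves them, whereas a
0.85× frequency change is invisible to moment-based features. Under
this effect, perturbed walking lands on the trotting signature and
perturbed eating on the biting/holding signature — a behaviour-specific
loss of predictability, exactly the phenomenon the bootstrap comparison
is designed to detect — while the four sedentary postures are untouched
controls.

Bouts are scheduled sequentially with exponential durations (floored at
2 s so every bout spans whole epochs). When a per-class minimum time is
requested (the benchmark reserves 3 s per required epoch), quota bouts
capped at the quota are scheduled first, the remainder is filled by
weighted draws trimmed to the horizon, and the shuffle is redrawn
(bounded retries) if truncation would push a class's quota past the
trace end. Five-spike calibration taps are injected at the trace start
and end.

## Study conditions and problem sizes

The default benchmark simulates four independent traces — train and
test for each treatment — of 6,000 s (train) and 3,000 s (test) at
50 Hz, i.e. ~6,000/~3,000 epochs per table, with every behaviour
guaranteed at least 10 epochs per table. These durations are the
package's default study scale: large enough for every behaviour to
form stable codebook territory, small enough that the full
methodology — including a 200-replicate bootstrap that retrains the
SOM from scratch each replicate on 2,000-epoch draws — runs in minutes
on a single core. The headline experiment sizes (20,000-epoch training
subsets, 1,000 bootstrap replicates, 35 sample sizes × 10 replicates)
remain the defaults of the corresponding functions for users running at
full scale.

## Numerical choices and degenerate inputs

- Sampling uniformity tolerance: 1e-6 s per step; clock apply∘invert is
  identity to well below 1e-9 s.
- Percentiles: linear interpolation between order statistics.
- Constant features: excluded from SOM distances with a warning, kept
  in the table.
- Behaviours absent from a bootstrap test draw: NaN for that replicate,
  excluded from medians; a behaviour absent from every replicate gets
  an `undefined` verdict rather than one of the three overlap verdicts.
- Empty labelled spans shorter than one epoch produce an empty feature
  table with a warning, not an error.
- All randomness flows through `numpy.random.default_rng` seeds;
  per-replicate seeds are spawned from a master generator so sweeps are
  reproducible and individually re-runnable.

## Known limitations

- The simulator's stationary, piecewise-constant bouts understate the
  within-class variability of real accelerometry; real-data accuracy
  will be lower than synthetic-benchmark accuracy.
- Epochs straddling bout boundaries mix two behaviours under a majority
  label; they are a small fraction of epochs at the default bout
  lengths and bound the achievable accuracy below 1.
- The bootstrap CIs quantify training-resampling variability only; the
  two test sets are fixed. With modest test sets, two independently
  generated test traces differ in composition, so rare, mutually
  confusable behaviours (e.g. jumping vs pouncing) can occasionally
  return an equivocal — or even significant — verdict under a null
  effect. The planted-effect signal (accuracy drops of 0.05–0.15) is an
  order of magnitude larger than this composition noise; larger test
  sets shrink it further.
- Only linear clock drift is supported.
- The SOM is the online variant; batch and toroidal variants are out of
  scope.
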