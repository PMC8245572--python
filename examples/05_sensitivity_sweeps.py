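"""Sample-size and grid-size sensitivity sweeps (scaled).

Shows the characteristic rise of sensitivity with training-set size and
enumerates the 4-9 grid search (36 configurations here run at reduced
training size). Larger grids give finer behaviour maps but need more
data per unit.
"""

import numpy as np

import somtag as st

bench = st.make_benchmark(seed=1)

results = st.sample_size_sweep(bench.train_off, sizes=[200, 1000, 5000], reps=3, seed=0)
print("training size -> median macro sensitivity:")
for size in (200, 1000, 5000):
    med = np.median([r.metrics.macro["sensitivity"] for r in results if r.axis == size])
    print(f"  {size:>6d}  {med:.3f}")

sweep = st.grid_sweep(
    bench.train_off, (4, 9), params=st.TrainParams(rlen=20), seed=0, train_n=500
)
best = max(sweep, key=lambda r: r.metrics.overall_accuracy)
print(f"\ngrid sweep: {len(sweep)} configurations; "
      f"best {best.axis} with overall accuracy {best.metrics.overall_accuracy:.3f}")
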