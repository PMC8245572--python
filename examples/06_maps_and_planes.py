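"""Codebook map and component planes.

Renders the trained SOM as a hexagonal map (units coloured by dominant
behaviour, thick boundaries from hierarchical clustering of the
codebook) and heat maps of four informative features across the grid.
Units close on the map have similar accelerometer signatures.
"""

import numpy as np

import somtag as st
from somtag.viz import plot_component_planes, plot_map

bench = st.make_benchmark(seed=1)
rng = np.random.default_rng(0)
idx = rng.choice(len(bench.train_off), 2000, replace=True)
model = st.train_supersom(bench.train_off.iloc[idx], st.make_grid(7, 7), seed=0)

clusters = st.cluster_codebook(model, k=12)
plot_map(model, clusters, "som_map.png")
plot_component_planes(model, ["sum_vdba", "max_z", "corr_xz", "mean_x"], "som_planes.png")
print("wrote som_map.png (codebook map, 49 hexagonal cells, 12 clusters)")
print("wrote som_planes.png (component planes for 4 features)")

plane = st.component_plane(model, "sum_vdba")
dom = np.argmax(model.codebook_act, axis=1)
print(f"sum_vdba peaks at unit {int(np.argmax(plane))} "
      f"({model.class_names[dom[int(np.argmax(plane))]]} territory)")
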