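"""SOM visualisations: codebook map with cluster boundaries, and
component-plane heat maps.

Figures are side artefacts of the analysis; all quantitative results
flow through CSV/JSON reports, never through pixels.
"""

from __future__ import annotations

import numpy as np
import matplotlib
from matplotlib import cm, colors as mcolors
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.patches import RegularPolygon

from .supersom import SuperSomModel, component_plane

_HEX_R = 1.0 / np.sqrt(3.0)  # circumradius for unit-spaced hexagons


def _draw_units(ax, model: SuperSomModel, face_values, cmap, norm):
    for (x, y), v in zip(model.grid.unit_coords, face_values):
        ax.add_patch(
            RegularPolygon(
                (x, y), numVertices=6, radius=_HEX_R,
                facecolor=cmap(norm(v)), edgecolor="white", linewidth=0.5,
            )
        )
    coords = model.grid.unit_coords
    ax.set_xlim(coords[:, 0].min() - 1, coords[:, 0].max() + 1)
    ax.set_ylim(coords[:, 1].min() - 1, coords[:, 1].max() + 1)
    ax.set_aspect("equal")
    ax.axis("off")


def plot_map(model: SuperSomModel, clusters: np.ndarray, out_path) -> None:
    """Codebook map: units coloured by dominant activity, thick black
    boundaries between units assigned to different clusters."""
    U = model.grid.n_units
    clusters = np.asarray(clusters)
    if clusters.shape != (U,):
        raise ValueError("clusters must assign one id per unit")
    dominant = np.argmax(model.codebook_act, axis=1)
    K = len(model.class_names)
    cmap = matplotlib.colormaps["tab20"].resampled(max(K, 2))
    norm = mcolors.Normalize(vmin=0, vmax=max(K - 1, 1))

    fig = Figure(figsize=(7, 6))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    _draw_units(ax, model, dominant, cmap, norm)

    coords = model.grid.unit_coords
    half_edge = _HEX_R / 2.0
    for i in range(U):
        for j in range(i + 1, U):
            if abs(model.grid.unit_dist[i, j] - 1.0) < 1e-6 and clusters[i] != clusters[j]:
                mid = (coords[i] + coords[j]) / 2.0
                d = coords[j] - coords[i]
                perp = np.array([-d[1], d[0]])
                perp = perp / np.linalg.norm(perp) * half_edge
                ax.plot(
                    [mid[0] - perp[0], mid[0] + perp[0]],
                    [mid[1] - perp[1], mid[1] + perp[1]],
                    color="black", linewidth=3, solid_capstyle="round",
                )
    handles = [
        RegularPolygon((0, 0), 6, radius=0.5, facecolor=cmap(norm(k)))
        for k in range(K)
    ]
    ax.legend(handles, model.class_names, loc="center left",
              bbox_to_anchor=(1.0, 0.5), fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)


def plot_component_planes(
    model: SuperSomModel,
    feature_names: list[str],
    out_path,
    shared_scale: bool = False,
) -> None:
    """One heat map per feature showing its codebook values on the grid."""
    planes = {name: component_plane(model, name) for name in feature_names}
    ncol = min(len(planes), 4) or 1
    nrow = int(np.ceil(len(planes) / ncol))
    fig = Figure(figsize=(3.2 * ncol, 3.0 * nrow))
    FigureCanvasAgg(fig)
    if shared_scale:
        allv = np.concatenate(list(planes.values()))
        vmin, vmax = float(allv.min()), float(allv.max())
    cmap = matplotlib.colormaps["viridis"]
    for k, (name, vals) in enumerate(planes.items()):
        ax = fig.add_subplot(nrow, ncol, k + 1)
        if not shared_scale:
            vmin, vmax = float(vals.min()), float(vals.max())
        if vmax <= vmin:
            vmax = vmin + 1e-12  # constant plane renders flat
        norm = mcolors.Normalize(vmin=vmin, vmax=vmax)
        _draw_units(ax, model, vals, cmap, norm)
        ax.set_title(name, fontsize=9)
        fig.colorbar(cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
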