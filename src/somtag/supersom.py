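"""Supervised Kohonen super self-organising map.

A super-SOM trains one shared grid of units against several data layers
at once. Here there are two: the *measurements* layer (the scaled
feature vectors, 26-dimensional by default) and the *activity* layer
(a one-hot encoding of the behaviour labels, 12-dimensional). During
training, the best-matching unit (BMU) for a sample minimises the
layer-weighted sum of squared Euclidean distances, each layer's distance
divided by a data-estimated scale so that layers of different
dimensionality contribute comparably. Both codebooks are pulled towards
the sample with the classic online update

    w <- w + alpha * h * (x - w)

with a linearly declining learning rate and a bubble (or Gaussian)
neighbourhood whose radius declines linearly from the 2/3 quantile of
inter-unit distances to zero. Prediction uses only the measurements
layer to find the BMU and reads the predicted class off the activity
codebook (argmax).

Everything is deterministic given (data, params, seed); ties in BMU
search and class argmax are broken by lowest index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .features import feature_columns
from .taxonomy import BEHAVIOURS

MODEL_FORMAT_VERSION = 1


class ModelValidationError(ValueError):
    """Serialised model fails internal consistency checks."""


@dataclass(frozen=True)
class SomGrid:
    """A 2-D grid of SOM units with precomputed inter-unit distances."""

    nx: int
    ny: int
    topology: str
    unit_coords: np.ndarray  # units × 2
    unit_dist: np.ndarray  # units × units Euclidean distances

    @property
    def n_units(self) -> int:
        return self.nx * self.ny


def make_grid(nx: int, ny: int, topology: str = "hexagonal") -> SomGrid:
    """Lay out an nx × ny unit grid.

    Hexagonal layout offsets every other row by 0.5 with row spacing
    sqrt(3)/2, so nearest neighbours sit at distance 1. Unit order is
    row-major (x varies fastest).
    """
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be positive")
    if topology not in ("hexagonal", "rectangular"):
        raise ValueError(f"unknown topology {topology!r}")
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny))
    cols = cols.ravel().astype(float)
    rows = rows.ravel().astype(float)
    if topology == "hexagonal":
        xs = cols + 0.5 * (rows % 2)
        ys = rows * (np.sqrt(3.0) / 2.0)
    else:
        xs, ys = cols, rows
    coords = np.column_stack([xs, ys])
    dist = cdist(coords, coords)
    return SomGrid(nx=nx, ny=ny, topology=topology, unit_coords=coords, unit_dist=dist)


def one_hot(labels, class_names) -> np.ndarray:
    """Rows × classes indicator matrix in class_names column order."""
    index = {c: j for j, c in enumerate(class_names)}
    labels = list(labels)
    out = np.zeros((len(labels), len(class_names)))
    for i, lab in enumerate(labels):
        try:
            out[i, index[lab]] = 1.0
        except KeyError:
            raise ValueError(f"label {lab!r} not in class_names") from None
    return out


@dataclass(frozen=True)
class TrainParams:
    """Online-training hyperparameters (reference-implementation defaults)."""

    rlen: int = 100
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    neighbourhood: str = "bubble"  # or "gaussian"
    radius_quantile: float = 2.0 / 3.0
    radius0: float | None = None  # override the quantile rule when set
    user_weights: tuple[float, float] = (1.0, 1.0)  # (measurements, activity)
    scale: bool = True


@dataclass
class SuperSomModel:
    grid: SomGrid
    codebook_meas: np.ndarray  # units × n_features (scaled space)
    codebook_act: np.ndarray  # units × n_classes
    class_names: list[str]
    feature_names: list[str]
    centre: np.ndarray
    spread: np.ndarray
    constant_mask: np.ndarray  # features excluded from distances
    dist_scale: tuple[float, float]  # per-layer mean squared data distance
    params: TrainParams
    seed: int


@dataclass(frozen=True)
class Prediction:
    unit: np.ndarray  # per-row best-matching unit index
    behaviour: list[str]  # per-row predicted class


@njit(cache=True)
def _online_train(X, A, cbm, cba, unit_dist, order, alphas, radii, wm, wa, sm, sa, gauss):
    n_units, dm = cbm.shape
    da = cba.shape[1]
    for t in range(order.size):
        i = order[t]
        best = 0
        bestd = np.inf
        for u in range(n_units):
            d = 0.0
            for j in range(dm):
                diff = X[i, j] - cbm[u, j]
                d += diff * diff
            acc = d / sm * wm
            d = 0.0
            for j in range(da):
                diff = A[i, j] - cba[u, j]
                d += diff * diff
            acc += d / sa * wa
            if acc < bestd:  # strict: ties keep the lowest unit index
                bestd = acc
                best = u
        alpha = alphas[t]
        r = radii[t]
        for u in range(n_units):
            g = unit_dist[best, u]
            if gauss:
                if r > 1e-12:
                    h = np.exp(-(g * g) / (2.0 * r * r))
                else:
                    h = 1.0 if g == 0.0 else 0.0
                if h < 1e-12:
                    continue
            else:
                if g > r:
                    continue
                h = 1.0
            ah = alpha * h
            for j in range(dm):
                cbm[u, j] += ah * (X[i, j] - cbm[u, j])
            for j in range(da):
                cba[u, j] += ah * (A[i, j] - cba[u, j])


def _mean_sq_pair_dist(M: np.ndarray, rng: np.random.Generator, cap: int = 100) -> float:
    """Mean off-diagonal squared Euclidean distance on a seeded subsample."""
    n = M.shape[0]
    if n < 2:
        return 1.0
    idx = rng.choice(n, size=min(n, cap), replace=False)
    sub = M[idx]
    d2 = cdist(sub, sub, "sqeuclidean")
    m = d2.shape[0]
    total = d2.sum() / (m * (m - 1))
    return float(total) if total > 0 else 1.0


def _resolve_classes(behaviours) -> list[str]:
    present = set(behaviours)
    if present <= set(BEHAVIOURS):
        return list(BEHAVIOURS)
    return sorted(present)


def train_supersom(
    table: pd.DataFrame,
    grid: SomGrid,
    params: TrainParams | None = None,
    seed: int = 0,
    class_names: list[str] | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    order: np.ndarray | None = None,
) -> SuperSomModel:
    """Train a two-layer super-SOM on a feature table.

    ``table`` must carry a ``behaviour`` column plus feature columns.
    ``init`` (codebooks in scaled space) and ``order`` (explicit sample
    presentation order) override the seeded defaults; they exist so the
    training loop can be replayed against independent oracles.
    """
    params = params or TrainParams()
    feats = feature_columns(table)
    if not feats:
        raise ValueError("feature table has no feature columns")
    X = table[feats].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 1:
        raise ValueError("empty feature table")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")

    if class_names is None:
        class_names = _resolve_classes(table["behaviour"])
    if len(set(class_names)) != len(class_names):
        raise ValueError("class_names must be unique")
    A = one_hot(table["behaviour"], class_names)

    if params.scale:
        centre = X.mean(axis=0)
        spread = X.std(axis=0)
    else:
        centre = np.zeros(X.shape[1])
        spread = np.ones(X.shape[1])
    constant = spread <= 1e-12
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) excluded from distances",
            stacklevel=2,
        )
    spread_safe = np.where(constant, 1.0, spread)
    Xs = (X - centre) / spread_safe
    Xs[:, constant] = 0.0

    rng = np.random.default_rng(seed)
    U = grid.n_units
    if init is None:
        idx = rng.choice(n, size=U, replace=n < U)
        cbm = Xs[idx].copy()
        cba = A[idx].copy()
    else:
        cbm = np.array(init[0], dtype=float)
        cba = np.array(init[1], dtype=float)
        if cbm.shape != (U, Xs.shape[1]) or cba.shape != (U, A.shape[1]):
            raise ValueError("init codebook shapes do not match grid/data")

    sm = _mean_sq_pair_dist(Xs, rng)
    sa = _mean_sq_pair_dist(A, rng)

    if order is None:
        order = np.concatenate([rng.permutation(n) for _ in range(params.rlen)])
    order = np.ascontiguousarray(order, dtype=np.int64)
    T = order.size

    if params.radius0 is not None:
        r0 = float(params.radius0)
    else:
        iu = np.triu_indices(U, k=1)
        r0 = float(np.quantile(grid.unit_dist[iu], params.radius_quantile)) if U > 1 else 0.0
    alphas = np.linspace(params.alpha_start, params.alpha_end, T)
    radii = np.linspace(r0, 0.0, T)

    wm, wa = params.user_weights
    if wm < 0 or wa < 0:
        raise ValueError("user weights must be non-negative")
    _online_train(
        Xs,
        A,
        cbm,
        cba,
        grid.unit_dist,
        order,
        alphas,
        radii,
        float(wm),
        float(wa),
        sm,
        sa,
        params.neighbourhood == "gaussian",
    )

    return SuperSomModel(
        grid=grid,
        codebook_meas=cbm,
        codebook_act=cba,
        class_names=list(class_names),
        feature_names=list(feats),
        centre=centre,
        spread=spread_safe,
        constant_mask=constant,
        dist_scale=(sm, sa),
        params=params,
        seed=seed,
    )


def _scale_features(model: SuperSomModel, table: pd.DataFrame) -> np.ndarray:
    missing = [f for f in model.feature_names if f not in table.columns]
    if missing:
        raise ValueError(f"feature table missing model features: {missing}")
    X = table[model.feature_names].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    Xs = (X - model.centre) / model.spread
    Xs[:, model.constant_mask] = 0.0
    return Xs


def predict(model: SuperSomModel, table: pd.DataFrame) -> Prediction:
    """Predict behaviours from measurement features alone.

    Rows are scaled by the model's stored training scaling; the BMU is
    found on the measurements layer only; the predicted class is the
    argmax of the BMU's activity codebook (ties: first class in
    class_names order).
    """
    Xs = _scale_features(model, table)
    d2 = cdist(Xs, model.codebook_meas, "sqeuclidean")
    bmu = np.argmin(d2, axis=1)  # ties -> lowest unit index
    unit_class = np.argmax(model.codebook_act, axis=1)  # ties -> first class
    return Prediction(
        unit=bmu, behaviour=[model.class_names[unit_class[u]] for u in bmu]
    )


def quantisation_error(model: SuperSomModel, table: pd.DataFrame) -> float:
    """Mean measurement-layer distance of rows to their BMU (scaled space)."""
    Xs = _scale_features(model, table)
    d2 = cdist(Xs, model.codebook_meas, "sqeuclidean")
    return float(np.sqrt(d2.min(axis=1)).mean())


def codebook_distances(model: SuperSomModel) -> np.ndarray:
    """Units × units distance over the concatenated weighted layers.

    Uses the same per-layer weighting and scale as the BMU search, so
    the matrix is the Euclidean metric of a weighted concatenation.
    """
    wm, wa = model.params.user_weights
    sm, sa = model.dist_scale
    dm = cdist(model.codebook_meas, model.codebook_meas, "sqeuclidean")
    da = cdist(model.codebook_act, model.codebook_act, "sqeuclidean")
    return np.sqrt(wm * dm / sm + wa * da / sa)


def cluster_codebook(model: SuperSomModel, k: int = 12) -> np.ndarray:
    """Complete-linkage hierarchical clustering of the codebook, cut at k.

    Returns per-unit cluster ids relabelled 1..k in order of first unit
    appearance.
    """
    U = model.grid.n_units
    if not 1 <= k <= U:
        raise ValueError(f"k must be in [1, {U}]")
    D = codebook_distances(model)
    Z = linkage(squareform(D, checks=False), method="complete")
    raw = fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out[i] = relabel[c]
    return out


def component_plane(model: SuperSomModel, feature_name: str) -> np.ndarray:
    """Per-unit codebook values for one feature, in original units."""
    try:
        j = model.feature_names.index(feature_name)
    except ValueError:
        raise ValueError(f"unknown feature {feature_name!r}") from None
    return model.codebook_meas[:, j] * model.spread[j] + model.centre[j]


def save_model(model: SuperSomModel, path) -> None:
    doc = {
        "version": MODEL_FORMAT_VERSION,
        "grid": {"nx": model.grid.nx, "ny": model.grid.ny, "topology": model.grid.topology},
        "codebooks": {
            "measurements": model.codebook_meas.tolist(),
            "activity": model.codebook_act.tolist(),
        },
        "scaling": {
            "centre": model.centre.tolist(),
            "spread": model.spread.tolist(),
            "constant_mask": model.constant_mask.astype(int).tolist(),
        },
        "class_names": model.class_names,
        "feature_names": model.feature_names,
        "dist_scale": list(model.dist_scale),
        "params": asdict(model.params),
        "seed": model.seed,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> SuperSomModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ModelValidationError(f"unsupported model version {doc.get('version')!r}")
    grid = make_grid(doc["grid"]["nx"], doc["grid"]["ny"], doc["grid"]["topology"])
    cbm = np.asarray(doc["codebooks"]["measurements"], dtype=float)
    cba = np.asarray(doc["codebooks"]["activity"], dtype=float)
    class_names = list(doc["class_names"])
    feature_names = list(doc["feature_names"])
    if cbm.shape != (grid.n_units, len(feature_names)):
        raise ModelValidationError("measurement codebook shape mismatch")
    if cba.shape != (grid.n_units, len(class_names)):
        raise ModelValidationError("activity codebook shape mismatch")
    p = doc["params"]
    params = TrainParams(
        rlen=p["rlen"],
        alpha_start=p["alpha_start"],
        alpha_end=p["alpha_end"],
        neighbourhood=p["neighbourhood"],
        radius_quantile=p["radius_quantile"],
        radius0=p["radius0"],
        user_weights=tuple(p["user_weights"]),
        scale=p["scale"],
    )
    return SuperSomModel(
        grid=grid,
        codebook_meas=cbm,
        codebook_act=cba,
        class_names=class_names,
        feature_names=feature_names,
        centre=np.asarray(doc["scaling"]["centre"], dtype=float),
        spread=np.asarray(doc["scaling"]["spread"], dtype=float),
        constant_mask=np.asarray(doc["scaling"]["constant_mask"], dtype=bool),
        dist_scale=tuple(doc["dist_scale"]),
        params=params,
        seed=int(doc["seed"]),
    )
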