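"""End-to-end pipeline: simulate → extract → train → predict → evaluate.

Every run writes its resolved configuration, seed and artefacts into a
run directory; reruns with the same configuration and seed reproduce the
CSV reports byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import RunConfig
from .evaluation import confusion_matrix, metrics
from .features import build_feature_table, write_feature_table
from .supersom import (
    TrainParams,
    cluster_codebook,
    make_grid,
    predict,
    save_model,
    train_supersom,
)
from .synthetic import TreatmentEffect, default_behaviour_library, simulate_trace
from .viz import plot_component_planes, plot_map

DEFAULT_PLANE_FEATURES = ["sum_vdba", "max_z", "corr_xz", "mean_x"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc

        return wrapper

    return deco


def train_params_from_config(config: RunConfig) -> TrainParams:
    return TrainParams(
        rlen=config.rlen,
        alpha_start=config.alpha_start,
        alpha_end=config.alpha_end,
        neighbourhood=config.neighbourhood,
    )


@_stage("simulate")
def _simulate(config: RunConfig, seed: int, duration: float, treatment: str):
    return simulate_trace(
        default_behaviour_library(),
        duration,
        treatment=treatment,
        effect=TreatmentEffect(),
        rate_hz=config.rate_hz,
        seed=seed,
    )


@_stage("extract")
def _extract(dataset, config: RunConfig):
    return build_feature_table(dataset.trace, dataset.intervals, profile=config.profile)


def run_pipeline(config: RunConfig, out_dir) -> dict[str, Path]:
    """Execute the full synthetic pipeline into ``out_dir``.

    Returns a name → path mapping of the artefacts written: resolved
    config, train/test feature tables, model, predictions, per-class
    metrics, JSON summary, codebook map and component planes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["config"] = out / "config.yaml"
    config.to_yaml(paths["config"])

    seeds = np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=3)
    train_ds = _simulate(config, int(seeds[0]), config.simulate_train_s, "bib_off")
    test_ds = _simulate(config, int(seeds[1]), config.simulate_test_s, "bib_off")
    train_table = _extract(train_ds, config)
    test_table = _extract(test_ds, config)
    paths["train_features"] = out / "train_features.csv"
    paths["test_features"] = out / "test_features.csv"
    write_feature_table(train_table, paths["train_features"])
    write_feature_table(test_table, paths["test_features"])

    try:
        grid = make_grid(config.grid_nx, config.grid_ny, config.topology)
        n = len(train_table)
        rng = np.random.default_rng(int(seeds[2]))
        idx = rng.choice(n, size=min(config.train_n, n), replace=True)
        model = train_supersom(
            train_table.iloc[idx], grid,
            params=train_params_from_config(config), seed=int(seeds[2]),
        )
    except Exception as exc:
        raise PipelineError(f"[train] {exc}") from exc
    paths["model"] = out / "model.json"
    save_model(model, paths["model"])

    try:
        pred = predict(model, test_table)
    except Exception as exc:
        raise PipelineError(f"[predict] {exc}") from exc
    paths["predictions"] = out / "predictions.csv"
    pred_df = test_table[["start_s", "behaviour"]].copy()
    pred_df["predicted"] = pred.behaviour
    pred_df["unit"] = pred.unit
    pred_df.to_csv(paths["predictions"], index=False, float_format="%.12g")

    try:
        cm = confusion_matrix(pred.behaviour, list(test_table["behaviour"]), model.class_names)
        m = metrics(cm)
    except Exception as exc:
        raise PipelineError(f"[evaluate] {exc}") from exc
    paths["metrics"] = out / "metrics.csv"
    m.per_class.rename_axis("behaviour").to_csv(paths["metrics"], float_format="%.12g")
    paths["summary"] = out / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "n_train": int(len(train_table)),
                "n_test": int(len(test_table)),
                "overall_accuracy": m.overall_accuracy,
                "macro": m.macro,
            },
            fh,
            indent=2,
            sort_keys=True,
        )

    try:
        clusters = cluster_codebook(model, k=min(12, model.grid.n_units))
        paths["map"] = out / "map.png"
        plot_map(model, clusters, paths["map"])
        planes = [f for f in DEFAULT_PLANE_FEATURES if f in model.feature_names]
        paths["planes"] = out / "planes.png"
        plot_component_planes(model, planes, paths["planes"])
    except Exception as exc:
        raise PipelineError(f"[figures] {exc}") from exc

    return paths
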