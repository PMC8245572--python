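"""Classifier evaluation: confusion matrices, per-class metrics,
sample-size and grid-size sensitivity sweeps, the bootstrap treatment
comparison, and a random-forest baseline.

Per-class metrics follow the standard one-vs-rest decomposition of a
K-class confusion matrix (rows = predicted, columns = observed):

    sensitivity = TP / (TP + FN)        precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)        accuracy    = (TP + TN) / total

Zero denominators yield NaN (an explicit undefined flag) and are
excluded from macro averages and bootstrap medians, never imputed.

The bootstrap comparison retrains the classifier on resampled training
draws and scores two test conditions with each replicate, summarising
per-behaviour performance by the median and a 2.5–97.5 percentile
interval. Verdicts follow interval-overlap rules: disjoint intervals are
*significant*; either median inside the other interval is
*no_difference*; anything else is *equivocal*.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .features import feature_columns
from .supersom import (
    SomGrid,
    SuperSomModel,
    TrainParams,
    make_grid,
    predict,
    train_supersom,
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """K×K counts; rows index predicted classes, columns observed."""

    class_names: list[str]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class one-vs-rest metrics plus overall and macro summaries.

    ``per_class`` is indexed by class with columns tp/fp/fn/tn and the
    four rates; undefined rates are NaN. ``macro`` holds NaN-excluding
    means of each rate.
    """

    per_class: pd.DataFrame
    overall_accuracy: float
    macro: dict[str, float]


@dataclass(frozen=True)
class SweepResult:
    axis: object  # sample size or (nx, ny)
    replicate: int
    seed: int
    metrics: ClassMetrics


@dataclass(frozen=True)
class BootstrapComparison:
    summary: pd.DataFrame  # behaviour, condition, median, ci_low, ci_high, n_defined
    verdicts: dict[str, str]
    metric: str
    n_boot: int
    condition_names: tuple[str, str]


def confusion_matrix(predicted, observed, class_names) -> ConfusionMatrix:
    predicted = list(predicted)
    observed = list(observed)
    if len(predicted) != len(observed):
        raise ValueError("predicted and observed must have equal length")
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for p, o in zip(predicted, observed):
        if p not in index or o not in index:
            raise ValueError(f"label outside class_names: {p!r}/{o!r}")
        counts[index[p], index[o]] += 1
    return ConfusionMatrix(class_names=list(class_names), counts=counts)


def class_counts(cm: ConfusionMatrix, cls: str) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, FP, FN, TN) for one class."""
    try:
        i = cm.class_names.index(cls)
    except ValueError:
        raise ValueError(f"unknown class {cls!r}") from None
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[i, :].sum()) - tp
    fn = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


def _rate(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """The four per-class metrics plus overall accuracy and macro means."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows = []
    for cls in cm.class_names:
        tp, fp, fn, tn = class_counts(cm, cls)
        rows.append(
            {
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "tn": tn,
                "sensitivity": _rate(tp, tp + fn),
                "precision": _rate(tp, tp + fp),
                "specificity": _rate(tn, tn + fp),
                "accuracy": _rate(tp + tn, tp + tn + fp + fn),
            }
        )
    per_class = pd.DataFrame(rows, index=list(cm.class_names))
    overall = float(np.trace(cm.counts)) / cm.total
    macro = {
        name: float(np.nanmean(per_class[name]))
        for name in ("sensitivity", "precision", "specificity", "accuracy")
    }
    return ClassMetrics(per_class=per_class, overall_accuracy=overall, macro=macro)


def evaluate_model(model: SuperSomModel, test: pd.DataFrame) -> ClassMetrics:
    """Predict a labelled test table and score it."""
    pred = predict(model, test)
    cm = confusion_matrix(pred.behaviour, list(test["behaviour"]), model.class_names)
    return metrics(cm)


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def sample_size_sweep(
    table: pd.DataFrame,
    sizes: list[int],
    reps: int = 10,
    grid: SomGrid | None = None,
    params: TrainParams | None = None,
    seed: int = 0,
) -> list[SweepResult]:
    """Train-set-size sensitivity sweep.

    For each size × replicate, a seeded random subsample drawn *with
    replacement* trains a model; all rows not drawn form the test set.
    """
    if not sizes:
        raise ValueError("sizes must be non-empty")
    grid = grid or make_grid(7, 7)
    master = np.random.default_rng(seed)
    n = len(table)
    results = []
    for size in sizes:
        for rep in range(reps):
            rs = _spawn_seed(master)
            rng = np.random.default_rng(rs)
            idx = rng.choice(n, size=size, replace=True)
            test_mask = np.ones(n, dtype=bool)
            test_mask[np.unique(idx)] = False
            train = table.iloc[idx]
            test = table.iloc[np.flatnonzero(test_mask)]
            model = train_supersom(train, grid, params=params, seed=rs)
            results.append(
                SweepResult(axis=size, replicate=rep, seed=rs, metrics=evaluate_model(model, test))
            )
    return results


def grid_sweep(
    table: pd.DataFrame,
    side_range: tuple[int, int] = (4, 9),
    params: TrainParams | None = None,
    seed: int = 0,
    train_n: int = 2000,
    topology: str = "hexagonal",
) -> list[SweepResult]:
    """Grid-dimension sensitivity: one model per (nx, ny) pair.

    The default 4..9 range enumerates the full 6×6 = 36 Cartesian
    product. Training rows are a seeded with-replacement draw of
    ``train_n``; undrawn rows are the test set.
    """
    lo, hi = side_range
    if hi < lo:
        raise ValueError("empty side range")
    master = np.random.default_rng(seed)
    n = len(table)
    results = []
    for nx, ny in product(range(lo, hi + 1), repeat=2):
        rs = _spawn_seed(master)
        rng = np.random.default_rng(rs)
        idx = rng.choice(n, size=min(train_n, n), replace=True)
        test_mask = np.ones(n, dtype=bool)
        test_mask[np.unique(idx)] = False
        model = train_supersom(table.iloc[idx], make_grid(nx, ny, topology), params=params, seed=rs)
        results.append(
            SweepResult(
                axis=(nx, ny),
                replicate=0,
                seed=rs,
                metrics=evaluate_model(model, table.iloc[np.flatnonzero(test_mask)]),
            )
        )
    return results


def overlap_verdict(
    median_a: float,
    ci_a: tuple[float, float],
    median_b: float,
    ci_b: tuple[float, float],
) -> str:
    """Interval-overlap verdict for two (median, CI) summaries."""
    vals = [median_a, *ci_a, median_b, *ci_b]
    if any(not np.isfinite(v) for v in vals):
        return "undefined"
    lo_a, hi_a = ci_a
    lo_b, hi_b = ci_b
    if hi_a < lo_b or hi_b < lo_a:
        return "significant"
    if lo_b <= median_a <= hi_b or lo_a <= median_b <= hi_a:
        return "no_difference"
    return "equivocal"


def _per_class_values(
    model: SuperSomModel, test: pd.DataFrame, metric: str
) -> np.ndarray:
    """Per-class metric values on one test set; NaN for absent classes."""
    m = evaluate_model(model, test)
    vals = m.per_class[metric].to_numpy(dtype=float).copy()
    observed = m.per_class["tp"] + m.per_class["fn"]  # column sums
    vals[observed.to_numpy() == 0] = np.nan
    return vals


def bootstrap_compare(
    train_pool: pd.DataFrame,
    test_a: pd.DataFrame,
    test_b: pd.DataFrame,
    train_n: int = 20000,
    n_boot: int = 1000,
    grid: SomGrid | None = None,
    params: TrainParams | None = None,
    seed: int = 0,
    metric: str = "accuracy",
    condition_names: tuple[str, str] = ("bib_off", "bib_on"),
) -> BootstrapComparison:
    """Bootstrap test for behaviour-specific performance change.

    Each replicate draws ``train_n`` rows with replacement from
    ``train_pool``, trains a model, and scores the per-behaviour
    ``metric`` on both test conditions. Per behaviour × condition the
    median and 2.5/97.5 percentile CI are reported (linear interpolation
    between order statistics, NaN replicates excluded), and a verdict is
    issued per behaviour from the overlap rules.
    """
    fa, fb = feature_columns(test_a), feature_columns(test_b)
    if set(fa) != set(feature_columns(train_pool)) or set(fa) != set(fb):
        raise ValueError("train pool and test sets must share feature names")
    grid = grid or make_grid(7, 7)
    master = np.random.default_rng(seed)
    n = len(train_pool)
    if n == 0:
        raise ValueError("empty training pool")
    acc_a = []
    acc_b = []
    class_names = None
    for _ in range(n_boot):
        rs = _spawn_seed(master)
        rng = np.random.default_rng(rs)
        idx = rng.choice(n, size=train_n, replace=True)
        model = train_supersom(train_pool.iloc[idx], grid, params=params, seed=rs)
        class_names = model.class_names
        acc_a.append(_per_class_values(model, test_a, metric))
        acc_b.append(_per_class_values(model, test_b, metric))
    acc_a = np.asarray(acc_a)
    acc_b = np.asarray(acc_b)

    rows = []
    verdicts = {}
    for j, cls in enumerate(class_names):
        summaries = []
        for cond, vals in zip(condition_names, (acc_a[:, j], acc_b[:, j])):
            defined = vals[np.isfinite(vals)]
            if defined.size:
                med = float(np.median(defined))
                lo, hi = (float(v) for v in np.percentile(defined, [2.5, 97.5]))
            else:
                med = lo = hi = float("nan")
            summaries.append((med, lo, hi))
            rows.append(
                {
                    "behaviour": cls,
                    "condition": cond,
                    "median": med,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n_defined": int(defined.size),
                }
            )
        (ma, la, ha), (mb, lb, hb) = summaries
        verdicts[cls] = overlap_verdict(ma, (la, ha), mb, (lb, hb))
    return BootstrapComparison(
        summary=pd.DataFrame(rows),
        verdicts=verdicts,
        metric=metric,
        n_boot=n_boot,
        condition_names=condition_names,
    )


def rf_baseline(
    train: pd.DataFrame,
    test: pd.DataFrame,
    n_trees: int = 100,
    mtry: int = 4,
    seed: int = 0,
) -> ClassMetrics:
    """Random-forest comparator (the one off-the-shelf model call).

    ``mtry`` is the number of candidate features per split.
    """
    try:
        from sklearn.ensemble import RandomForestClassifier
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("rf_baseline requires scikit-learn") from exc
    feats = feature_columns(train)
    if set(feats) != set(feature_columns(test)):
        raise ValueError("train and test must share feature names")
    clf = RandomForestClassifier(n_estimators=n_trees, max_features=mtry, random_state=seed)
    clf.fit(train[feats].to_numpy(), list(train["behaviour"]))
    pred = list(clf.predict(test[feats].to_numpy()))
    classes = sorted(set(train["behaviour"]) | set(test["behaviour"]))
    return metrics(confusion_matrix(pred, list(test["behaviour"]), classes))


def side_by_side(som: ClassMetrics, rf: ClassMetrics, metric: str = "accuracy") -> pd.DataFrame:
    """Per-behaviour SOM vs RF comparison table."""
    df = pd.DataFrame(
        {
            "som": som.per_class[metric],
            "rf": rf.per_class[metric],
        }
    )
    df.index.name = "behaviour"
    return df
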