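"""Epoch segmentation and per-epoch feature summarisation.

Labelled traces are cut into fixed-duration epochs (1 s = 50 samples at
50 Hz), each labelled with the behaviour occurring most frequently among
its samples. Every epoch is then summarised by a named feature profile;
the default ``galea26`` profile has exactly 26 variables:

* per-axis mean, min, max and standard deviation of the raw samples (12)
* SMA — signal magnitude area, the mean over the epoch of
  ``|dx|+|dy|+|dz|`` computed on gravity-free (dynamic) samples (1)
* max and sum of per-sample ODBA, ``|dx|+|dy|+|dz|`` (2)
* max and sum of per-sample VDBA, ``sqrt(dx²+dy²+dz²)`` (2)
* Pearson correlations between axis pairs XY, YZ, XZ (3)
* per-axis skewness (Fisher–Pearson g1) and excess kurtosis (g2), both
  with the biased N denominator (6)

The dynamic (gravity-free) component subtracts a centred running-mean
estimate of the static acceleration (default 2 s window). Zero-variance
axes yield correlation/skewness/kurtosis of 0 by convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_sync import LabelInterval, RawTrace
from .taxonomy import BEHAVIOURS, TREATMENTS


class ConfigurationError(ValueError):
    """Epoch/rate combination is invalid (non-integral samples per epoch)."""


META_COLUMNS = ("start_s", "behaviour", "treatment")

_AXES = ("x", "y", "z")

_ALL_FEATURES = (
    [f"mean_{a}" for a in _AXES]
    + [f"min_{a}" for a in _AXES]
    + [f"max_{a}" for a in _AXES]
    + [f"sd_{a}" for a in _AXES]
    + ["sma", "max_odba", "sum_odba", "max_vdba", "sum_vdba"]
    + ["corr_xy", "corr_yz", "corr_xz"]
    + [f"skew_{a}" for a in _AXES]
    + [f"kurt_{a}" for a in _AXES]
    + ["min_odba", "min_vdba"]
)

#: Registered feature profiles: name -> ordered tuple of feature names.
PROFILES: dict[str, tuple[str, ...]] = {
    "galea26": tuple(_ALL_FEATURES[:26]),
    "galea_full": tuple(_ALL_FEATURES),
}


def register_profile(name: str, feature_names: tuple[str, ...]) -> None:
    """Register a custom feature profile (a subset of the computed set)."""
    unknown = set(feature_names) - set(_ALL_FEATURES)
    if unknown:
        raise ValueError(f"unknown features: {sorted(unknown)}")
    PROFILES[name] = tuple(feature_names)


def profile_features(profile: str) -> tuple[str, ...]:
    try:
        return PROFILES[profile]
    except KeyError:
        raise ValueError(
            f"unknown profile {profile!r}; registered: {sorted(PROFILES)}"
        ) from None


@dataclass(frozen=True)
class Epoch:
    """One fixed-duration window of samples with its majority label."""

    samples: np.ndarray  # L×3 acceleration in g
    start_s: float
    behaviour: str
    treatment: str


def _samples_per(rate_hz: float, duration_s: float, what: str) -> int:
    n = rate_hz * duration_s
    if abs(n - round(n)) > 1e-9:
        raise ConfigurationError(
            f"{what} of {duration_s} s is not a whole number of samples at {rate_hz} Hz"
        )
    return int(round(n))


def _modal_first(window: np.ndarray) -> int:
    """Mode of integer codes; ties broken by first occurrence in the window."""
    vals, first, counts = np.unique(window, return_index=True, return_counts=True)
    best = np.flatnonzero(counts == counts.max())
    return int(vals[best[np.argmin(first[best])]])


def _segment_indices(
    trace: RawTrace,
    intervals: list[LabelInterval],
    epoch_s: float,
    stride_s: float | None,
):
    """Window start indices plus modal behaviour/treatment codes per window.

    Windows are cut within each maximal contiguous labelled span,
    starting at the span's first sample; trailing partial windows are
    dropped. Intervals map to samples half-open: sample i belongs to
    [start, end) iff start <= t_i < end.
    """
    L = _samples_per(trace.rate_hz, epoch_s, "epoch")
    stride = L if stride_s is None else _samples_per(trace.rate_hz, stride_s, "stride")
    if stride < 1:
        raise ConfigurationError("stride must be at least one sample")

    n = len(trace)
    beh_code = np.full(n, -1, dtype=np.int64)
    trt_code = np.full(n, -1, dtype=np.int64)
    beh_index = {b: i for i, b in enumerate(BEHAVIOURS)}
    trt_index = {t: i for i, t in enumerate(TREATMENTS)}
    for iv in intervals:
        i0 = int(np.searchsorted(trace.times, iv.start_s, side="left"))
        i1 = int(np.searchsorted(trace.times, iv.end_s, side="left"))
        beh_code[i0:i1] = beh_index[iv.behaviour]
        trt_code[i0:i1] = trt_index[iv.treatment]

    labelled = beh_code >= 0
    starts: list[int] = []
    behs: list[int] = []
    trts: list[int] = []
    # contiguous labelled runs
    edges = np.flatnonzero(np.diff(np.concatenate([[0], labelled.view(np.int8), [0]])))
    for run_start, run_stop in zip(edges[::2], edges[1::2]):
        pos = run_start
        while pos + L <= run_stop:
            starts.append(pos)
            behs.append(_modal_first(beh_code[pos : pos + L]))
            trts.append(_modal_first(trt_code[pos : pos + L]))
            pos += stride
    if not starts:
        warnings.warn("no labelled span long enough for a single epoch", stacklevel=3)
    return (
        np.asarray(starts, dtype=np.int64),
        np.asarray(behs, dtype=np.int64),
        np.asarray(trts, dtype=np.int64),
        L,
    )


def segment_epochs(
    trace: RawTrace,
    intervals: list[LabelInterval],
    epoch_s: float = 1.0,
    stride_s: float | None = None,
) -> list[Epoch]:
    """Cut a labelled trace into majority-labelled epochs."""
    starts, behs, trts, L = _segment_indices(trace, intervals, epoch_s, stride_s)
    xyz = trace.xyz
    return [
        Epoch(
            samples=xyz[s : s + L],
            start_s=float(trace.times[s]),
            behaviour=BEHAVIOURS[b],
            treatment=TREATMENTS[t],
        )
        for s, b, t in zip(starts, behs, trts)
    ]


def static_component(trace: RawTrace, window_s: float = 2.0) -> np.ndarray:
    """Per-sample static (gravitational) acceleration estimate, n×3.

    Centred running mean per axis; edge windows are truncated. For an
    even window length the extra sample sits on the left of the centre.
    """
    if window_s < 2.0 / trace.rate_hz:
        raise ValueError("window_s must span at least two samples")
    w = int(round(trace.rate_hz * window_s))
    df = pd.DataFrame(trace.xyz)
    return df.rolling(w, center=True, min_periods=1).mean().to_numpy()


def dynamic_samples(epoch_block: np.ndarray, static_block: np.ndarray):
    """Dynamic (gravity-free) samples plus per-sample ODBA and VDBA.

    Returns ``(dyn, odba_t, vdba_t)`` where ``dyn = epoch − static``,
    ``odba_t = |dx|+|dy|+|dz|`` and ``vdba_t = sqrt(dx²+dy²+dz²)``.
    """
    epoch_block = np.asarray(epoch_block, dtype=float)
    static_block = np.asarray(static_block, dtype=float)
    if epoch_block.shape != static_block.shape:
        raise ValueError("epoch and static blocks must have the same shape")
    dyn = epoch_block - static_block
    odba_t = np.sum(np.abs(dyn), axis=-1)
    vdba_t = np.sqrt(np.sum(dyn**2, axis=-1))
    return dyn, odba_t, vdba_t


def _compute_all(raw: np.ndarray, static: np.ndarray) -> dict[str, np.ndarray]:
    """All registered features for a batch of windows.

    ``raw`` and ``static`` are (n_epochs, L, 3). Returns name -> (n,)
    arrays covering every feature any profile may select.
    """
    dyn, odba_t, vdba_t = dynamic_samples(raw, static)
    mean = raw.mean(axis=1)
    centred = raw - mean[:, None, :]
    m2 = np.mean(centred**2, axis=1)
    m3 = np.mean(centred**3, axis=1)
    m4 = np.mean(centred**4, axis=1)
    sd = np.sqrt(m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1.0) ** 2 - 3.0, 0.0)

    def corr(i: int, j: int) -> np.ndarray:
        cov = np.mean(centred[:, :, i] * centred[:, :, j], axis=1)
        denom = sd[:, i] * sd[:, j]
        return np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)

    out: dict[str, np.ndarray] = {}
    for k, a in enumerate(_AXES):
        out[f"mean_{a}"] = mean[:, k]
        out[f"min_{a}"] = raw[:, :, k].min(axis=1)
        out[f"max_{a}"] = raw[:, :, k].max(axis=1)
        out[f"sd_{a}"] = sd[:, k]
        out[f"skew_{a}"] = skew[:, k]
        out[f"kurt_{a}"] = kurt[:, k]
    out["sma"] = odba_t.mean(axis=1)
    out["max_odba"] = odba_t.max(axis=1)
    out["sum_odba"] = odba_t.sum(axis=1)
    out["min_odba"] = odba_t.min(axis=1)
    out["max_vdba"] = vdba_t.max(axis=1)
    out["sum_vdba"] = vdba_t.sum(axis=1)
    out["min_vdba"] = vdba_t.min(axis=1)
    out["corr_xy"] = corr(0, 1)
    out["corr_yz"] = corr(1, 2)
    out["corr_xz"] = corr(0, 2)
    return out


def extract_features(
    epoch: Epoch, static_block: np.ndarray, profile: str = "galea26"
) -> dict[str, float]:
    """Feature vector for one epoch as an ordered name -> value mapping."""
    names = profile_features(profile)
    samples = np.asarray(epoch.samples, dtype=float)
    static_block = np.asarray(static_block, dtype=float)
    if samples.shape != static_block.shape:
        raise ValueError("epoch sample-count mismatch with static block")
    all_feats = _compute_all(samples[None, :, :], static_block[None, :, :])
    vec = {name: float(all_feats[name][0]) for name in names}
    if not all(np.isfinite(v) for v in vec.values()):
        raise ValueError("non-finite feature value")
    return vec


def build_feature_table(
    trace: RawTrace,
    intervals: list[LabelInterval],
    profile: str = "galea26",
    epoch_s: float = 1.0,
    stride_s: float | None = None,
    static_window_s: float = 2.0,
) -> pd.DataFrame:
    """One feature row per epoch, ordered by start time.

    Returns a DataFrame with columns ``start_s, behaviour, treatment``
    followed by the profile's features in profile order; the feature
    name list is also stored in ``df.attrs["feature_names"]``. The
    static component is estimated once on the full trace.
    """
    names = profile_features(profile)
    starts, behs, trts, L = _segment_indices(trace, intervals, epoch_s, stride_s)
    static = static_component(trace, window_s=static_window_s)
    if starts.size == 0:
        df = pd.DataFrame(columns=[*META_COLUMNS, *names])
    else:
        idx = starts[:, None] + np.arange(L)[None, :]
        raw_wins = trace.xyz[idx]  # (n, L, 3)
        static_wins = static[idx]
        feats = _compute_all(raw_wins, static_wins)
        df = pd.DataFrame(
            {
                "start_s": trace.times[starts],
                "behaviour": [BEHAVIOURS[b] for b in behs],
                "treatment": [TREATMENTS[t] for t in trts],
                **{name: feats[name] for name in names},
            }
        )
    df.attrs["feature_names"] = list(names)
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a feature table (metadata excluded)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.attrs["feature_names"] = feature_columns(df)
    return df


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")
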