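"""Synthetic ethogram simulator: seeded, labelled tri-axial traces.

Each of the 12 behaviours is generated from a harmonic + burst + noise
family: a fixed gravity orientation (1 g), optional per-axis sinusoids
at a gait frequency with fixed inter-axis phase offsets, optional short
Gaussian burst pulses (jumps, pounces), and white Gaussian noise. This
family is chosen because the in-scope features (moments, ODBA/VDBA,
axis correlations) respond to exactly these degrees of freedom —
orientation moves the means, amplitude moves spreads and ODBA/VDBA,
bursts move the maxima, phase offsets move the correlations. No claim
of biomechanical realism is made.

Behaviour bouts are drawn sequentially with exponential durations
(floored at 2 s so each bout spans whole epochs); labels record the true
bout schedule exactly. Five-spike calibration tap bursts are injected at
trace start and end. All samples are clipped to the logger's ±8 g
dynamic range.

The treatment effect emulates a prey-protector bib altering gait: for
affected behaviours under ``bib_on``, harmonic amplitudes and the gait
frequency are multiplied and per-sample phase jitter is added. The
jitter degrades inter-axis coordination, which is the channel through
which the effect reaches the correlation features (a moderate frequency
change alone is nearly invisible to moment-based features).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .features import build_feature_table
from .io_sync import LabelInterval, RawTrace
from .taxonomy import BEHAVIOURS, validate_behaviour

#: Logger dynamic range in g.
CLIP_G = 8.0

_BURST_DIRECTION = np.array([0.7, 0.3, 1.0])


class SizingError(ValueError):
    """Requested class minimum unreachable within the trace duration."""


@dataclass(frozen=True)
class BehaviourSpec:
    """Generative parameters for one behaviour."""

    name: str
    group: str
    gravity_orientation: tuple[float, float, float]  # unit vector
    gait_freq_hz: float
    amplitudes: tuple[float, float, float]  # per-axis harmonic amplitude, g
    phase_offsets: tuple[float, float, float]  # per-axis phase, rad
    burst: tuple[float, float, float] | None  # (rate per s, peak g, width s)
    noise_sd: float  # g
    mean_bout_s: float
    weight: float  # relative bout-selection probability
    phase_jitter_sd: float = 0.0  # rad; intrinsic gait incoherence

    def __post_init__(self) -> None:
        validate_behaviour(self.name)
        g = np.asarray(self.gravity_orientation, dtype=float)
        if abs(np.linalg.norm(g) - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: gravity_orientation must be a unit vector")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError(f"{self.name}: amplitudes must be non-negative")


@dataclass(frozen=True)
class TreatmentEffect:
    """Signal perturbation applied to affected behaviours under bib_on."""

    affected_behaviours: frozenset[str] = frozenset({"walking", "eating_drinking"})
    amplitude_multiplier: float = 1.3
    frequency_multiplier: float = 0.85
    phase_jitter_sd: float = 0.8  # rad, per sample per axis

    def __post_init__(self) -> None:
        if self.amplitude_multiplier <= 0 or self.frequency_multiplier <= 0:
            raise ValueError("multipliers must be positive")
        for b in self.affected_behaviours:
            validate_behaviour(b)

    @classmethod
    def null(cls) -> "TreatmentEffect":
        """Identity effect: bib_on statistically identical to bib_off."""
        return cls(amplitude_multiplier=1.0, frequency_multiplier=1.0, phase_jitter_sd=0.0)

    @property
    def is_null(self) -> bool:
        return (
            self.amplitude_multiplier == 1.0
            and self.frequency_multiplier == 1.0
            and self.phase_jitter_sd == 0.0
        )


@dataclass(frozen=True)
class SyntheticDataset:
    trace: RawTrace
    intervals: list[LabelInterval]
    seed: int
    spec_snapshot: dict


def _unit(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float)
    a = a / np.linalg.norm(a)
    return tuple(float(x) for x in a)


def default_behaviour_library(amplitude_scale: float = 1.0) -> list[BehaviourSpec]:
    """The 12-behaviour generative library (parameter table in the docs).

    ``amplitude_scale`` scales every harmonic amplitude and burst peak
    while noise is held fixed — a separability dial: larger values push
    the classes further apart relative to the noise floor.
    """
    s = amplitude_scale

    def amps(x, y, z):
        return (s * x, s * y, s * z)

    def burst(rate, peak, width):
        return (rate, s * peak, width)

    return [
        # --- sedentary: near-static, distinct postural orientations ---
        BehaviourSpec("lying", "sedentary", _unit((0.0, 0.70, 0.71)), 0.0,
                      amps(0, 0, 0), (0, 0, 0), None, 0.020, 40.0, 1.0),
        BehaviourSpec("sitting", "sedentary", _unit((0.35, 0.0, 0.94)), 0.0,
                      amps(0, 0, 0), (0, 0, 0), None, 0.020, 30.0, 1.0),
        BehaviourSpec("grooming", "sedentary", _unit((0.10, 0.30, 0.95)), 1.5,
                      amps(0.06, 0.10, 0.06), (0.0, 1.0, 3.0), None, 0.030, 20.0, 0.9),
        BehaviourSpec("watching", "sedentary", _unit((-0.30, 0.05, 0.95)), 0.0,
                      amps(0, 0, 0), (0, 0, 0), None, 0.025, 30.0, 1.0),
        # --- eating & locomotive: rhythmic, walk < trot in intensity ---
        BehaviourSpec("eating_drinking", "eating_locomotive", _unit((0.55, 0.0, 0.84)), 2.2,
                      amps(0.14, 0.07, 0.18), (0.0, 1.2, 3.0), None, 0.030, 20.0, 1.2),
        # trot sits one gait-intensity step (~1.3x) above walk: the two
        # gaits share limb phasing and differ mainly in stride vigour
        BehaviourSpec("walking", "eating_locomotive", _unit((0.05, 0.0, 1.0)), 1.8,
                      amps(0.32, 0.20, 0.42), (0.0, 1.6, 0.8), None, 0.040, 15.0, 1.2),
        BehaviourSpec("trotting", "eating_locomotive", _unit((0.08, 0.0, 1.0)), 3.2,
                      amps(0.416, 0.26, 0.546), (0.0, 1.6, 0.8), None, 0.050, 10.0, 0.8),
        # --- hunting: high intensity or bursty, deliberately scarcer ---
        BehaviourSpec("galloping", "hunting", _unit((0.12, 0.0, 1.0)), 4.2,
                      amps(1.30, 0.55, 1.60), (0.0, 1.2, 0.5), None, 0.080, 6.0, 0.25),
        BehaviourSpec("jumping", "hunting", _unit((0.0, 0.0, 1.0)), 0.0,
                      amps(0, 0, 0), (0, 0, 0), burst(1.2, 4.5, 0.12), 0.050, 5.0, 0.30),
        BehaviourSpec("pouncing", "hunting", _unit((0.45, 0.0, 0.89)), 2.5,
                      amps(0.15, 0.10, 0.20), (0.0, 0.5, 1.5), burst(0.8, 2.8, 0.20), 0.050, 5.0, 0.30),
        BehaviourSpec("swatting", "hunting", _unit((0.20, 0.12, 0.97)), 5.0,
                      amps(0.10, 0.50, 0.12), (0.0, 0.0, 1.0), None, 0.040, 8.0, 0.40),
        # bite/hold: head-down (eating-like) posture with fast low-amplitude
        # worrying of the prey; intrinsic phase jitter loosens axis coupling
        BehaviourSpec("biting_holding", "hunting", _unit((0.52, 0.08, 0.85)), 8.0,
                      amps(0.182, 0.091, 0.234), (0.0, 1.2, 3.0), None, 0.035, 10.0, 0.45,
                      phase_jitter_sd=0.8),
    ]


def _bout_signal(
    spec: BehaviourSpec,
    n: int,
    rate_hz: float,
    rng: np.random.Generator,
    perturbed: bool,
    effect: TreatmentEffect,
) -> np.ndarray:
    t = np.arange(n) / rate_hz
    sig = np.tile(np.asarray(spec.gravity_orientation), (n, 1))
    amps = np.asarray(spec.amplitudes, dtype=float)
    freq = spec.gait_freq_hz
    if perturbed:
        amps = amps * effect.amplitude_multiplier
        freq = freq * effect.frequency_multiplier
    if freq > 0 and amps.any():
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        phase = (
            2.0 * np.pi * freq * t[:, None]
            + phi0
            + np.asarray(spec.phase_offsets)[None, :]
        )
        jitter_sd = np.hypot(
            spec.phase_jitter_sd, effect.phase_jitter_sd if perturbed else 0.0
        )
        if jitter_sd > 0:
            phase = phase + rng.normal(0.0, jitter_sd, size=(n, 3))
        sig = sig + amps[None, :] * np.sin(phase)
    if spec.burst is not None:
        b_rate, b_peak, b_width = spec.burst
        if perturbed:
            b_peak = b_peak * effect.amplitude_multiplier
        dur_s = n / rate_hz
        k = rng.poisson(b_rate * dur_s)
        sigma = b_width / 3.0
        for _ in range(k):
            c = rng.uniform(0.0, dur_s)
            sign = rng.choice((-1.0, 1.0))
            pulse = sign * b_peak * np.exp(-((t - c) ** 2) / (2.0 * sigma**2))
            sig = sig + pulse[:, None] * _BURST_DIRECTION[None, :]
    sig = sig + rng.normal(0.0, spec.noise_sd, size=(n, 3))
    return sig


def _inject_taps(sig: np.ndarray, rate_hz: float, rng: np.random.Generator) -> None:
    """Five-spike tap bursts at trace start and end (in place)."""
    n = sig.shape[0]
    for t0 in (0.2, n / rate_hz - 0.8):
        for k in range(5):
            i = int(round((t0 + 0.1 * k) * rate_hz))
            if 0 <= i < n:
                sig[i, 2] += 6.0 * (1.0 if k % 2 == 0 else -1.0)


def _bout_schedule(
    library: list[BehaviourSpec],
    total_s: float,
    rng: np.random.Generator,
    min_class_s: float,
) -> list[tuple[int, float]]:
    """Sequential bout plan: (library index, duration s) pairs.

    When ``min_class_s`` > 0, each behaviour first receives quota bouts
    until its scheduled time reaches the quota; the rest of the trace is
    filled by weighted draws and the whole bout order is shuffled, so
    rare behaviours stay scarce but are never absent. Bouts scheduled
    past ``total_s`` are truncated, so the shuffle is redrawn (bounded
    retries) until every quota lands inside the horizon.
    """
    weights = np.array([s.weight for s in library], dtype=float)
    weights = weights / weights.sum()
    bouts: list[tuple[int, float]] = []
    scheduled = 0.0
    if min_class_s > 0:
        for k, spec in enumerate(library):
            acc = 0.0
            while acc < min_class_s:
                # quota bouts capped at the quota so the schedule cannot
                # blow far past the requested horizon
                d = max(2.0, min(rng.exponential(spec.mean_bout_s), min_class_s))
                bouts.append((k, d))
                acc += d
                scheduled += d
    while scheduled < total_s:
        k = int(rng.choice(len(library), p=weights))
        d = max(2.0, rng.exponential(library[k].mean_bout_s))
        if scheduled + d > total_s:
            d = max(2.0, total_s - scheduled)
        bouts.append((k, d))
        scheduled += d
    for _ in range(50):
        rng.shuffle(bouts)
        if min_class_s <= 0:
            break
        within = np.zeros(len(library))
        t = 0.0
        for k, d in bouts:
            within[k] += min(d, max(0.0, total_s - t))
            t += d
        if np.all(within >= np.minimum(min_class_s, total_s / len(library))):
            break
    return bouts


def simulate_trace(
    library: list[BehaviourSpec],
    total_s: float,
    treatment: str = "bib_off",
    effect: TreatmentEffect | None = None,
    rate_hz: float = 50.0,
    seed: int = 0,
    include_taps: bool = True,
    min_class_s: float = 0.0,
) -> SyntheticDataset:
    """Simulate a labelled trace of ``total_s`` seconds.

    The treatment effect is applied only when ``treatment == "bib_on"``
    and the bout's behaviour is in the effect's affected set. Labels
    tile the trace without overlap and are exact: interval boundaries
    land on sample times. ``min_class_s`` reserves a minimum scheduled
    time per behaviour (see :func:`_bout_schedule`).
    """
    if total_s <= 0:
        raise ValueError("total_s must be positive")
    effect = effect if effect is not None else TreatmentEffect()
    rng = np.random.default_rng(seed)
    n_total = int(round(total_s * rate_hz))
    schedule = _bout_schedule(library, total_s, rng, min_class_s)

    sig = np.empty((n_total, 3))
    intervals: list[LabelInterval] = []
    pos = 0
    for k, dur_s in schedule:
        if pos >= n_total:
            break
        spec = library[k]
        dur_n = min(int(round(dur_s * rate_hz)), n_total - pos)
        if dur_n == 0:
            continue
        perturbed = (
            treatment == "bib_on" and spec.name in effect.affected_behaviours
        )
        sig[pos : pos + dur_n] = _bout_signal(spec, dur_n, rate_hz, rng, perturbed, effect)
        intervals.append(
            LabelInterval(
                start_s=pos / rate_hz,
                end_s=(pos + dur_n) / rate_hz,
                behaviour=spec.name,
                treatment=treatment,
            )
        )
        pos += dur_n

    if pos < n_total:
        # rounding shortfall: extend the last bout to the horizon
        spec = {s.name: s for s in library}[intervals[-1].behaviour]
        perturbed = treatment == "bib_on" and spec.name in effect.affected_behaviours
        sig[pos:n_total] = _bout_signal(
            spec, n_total - pos, rate_hz, rng, perturbed, effect
        )
        intervals[-1] = replace(intervals[-1], end_s=n_total / rate_hz)
        pos = n_total

    if include_taps:
        _inject_taps(sig, rate_hz, rng)
    np.clip(sig, -CLIP_G, CLIP_G, out=sig)

    trace = RawTrace(
        times=np.arange(n_total) / rate_hz,
        x=sig[:, 0],
        y=sig[:, 1],
        z=sig[:, 2],
        rate_hz=rate_hz,
    )
    snapshot = {
        "library": [asdict(s) for s in library],
        "effect": {
            "affected_behaviours": sorted(effect.affected_behaviours),
            "amplitude_multiplier": effect.amplitude_multiplier,
            "frequency_multiplier": effect.frequency_multiplier,
            "phase_jitter_sd": effect.phase_jitter_sd,
        },
        "total_s": total_s,
        "treatment": treatment,
        "rate_hz": rate_hz,
        "include_taps": include_taps,
        "min_class_s": min_class_s,
    }
    return SyntheticDataset(trace=trace, intervals=intervals, seed=seed, spec_snapshot=snapshot)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study conditions for the default synthetic benchmark."""

    train_s: float = 6000.0
    test_s: float = 3000.0
    rate_hz: float = 50.0
    effect: TreatmentEffect = field(default_factory=TreatmentEffect)
    profile: str = "galea26"
    amplitude_scale: float = 1.0
    min_epochs_per_class: int = 10


@dataclass(frozen=True)
class SyntheticBenchmark:
    """Feature tables for both treatments, train and test."""

    train_off: object  # FeatureTable (pandas DataFrame)
    train_on: object
    test_off: object
    test_on: object
    config: BenchmarkConfig
    seed: int


def _features_for(dataset: SyntheticDataset, profile: str):
    return build_feature_table(dataset.trace, dataset.intervals, profile=profile)


def make_benchmark(config: BenchmarkConfig | None = None, seed: int = 0) -> SyntheticBenchmark:
    """Simulate both treatments and pipe them through feature extraction.

    Four independent traces are generated (train/test × off/on) from
    seeds derived from ``seed``. Raises :class:`SizingError` when any
    behaviour falls below ``min_epochs_per_class`` in any table.
    """
    config = config or BenchmarkConfig()
    library = default_behaviour_library(config.amplitude_scale)
    sub = np.random.default_rng(seed).integers(0, 2**31 - 1, size=4)
    tables = {}
    for (name, treatment, dur), s in zip(
        [
            ("train_off", "bib_off", config.train_s),
            ("train_on", "bib_on", config.train_s),
            ("test_off", "bib_off", config.test_s),
            ("test_on", "bib_on", config.test_s),
        ],
        sub,
    ):
        ds = simulate_trace(
            library,
            dur,
            treatment=treatment,
            effect=config.effect,
            rate_hz=config.rate_hz,
            seed=int(s),
            min_class_s=3.0 * config.min_epochs_per_class,
        )
        table = _features_for(ds, config.profile)
        counts = table["behaviour"].value_counts()
        for b in BEHAVIOURS:
            if counts.get(b, 0) < config.min_epochs_per_class:
                raise SizingError(
                    f"{name}: behaviour {b!r} has {counts.get(b, 0)} epochs "
                    f"(< {config.min_epochs_per_class}); increase the trace "
                    "duration or the behaviour's selection weight"
                )
        tables[name] = table
    return SyntheticBenchmark(seed=seed, config=config, **tables)
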