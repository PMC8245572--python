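"""Trace/label I/O, tap-event detection and clock synchronisation.

Accelerometer loggers and the video reference run on independent clocks;
the device clock additionally drifts (manufacturer specification on the
order of 0.18 s per hour). Calibration taps — short bursts of hard raps
on the device, visible both on video and as large acceleration spikes —
anchor the two clocks. A linear clock model (offset + drift) is fitted to
the paired tap times and used to map video-annotated label intervals onto
device time.

Conventions: time is seconds as floats; label intervals are half-open
``[start, end)`` when mapped to samples; acceleration is in units of g.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .taxonomy import validate_behaviour, validate_treatment

#: Maximum deviation of any time step from the nominal step, in seconds.
UNIFORMITY_TOL_S = 1e-6


class FormatError(ValueError):
    """Input file does not have the expected columns/values."""


class SamplingError(ValueError):
    """Trace sampling is not uniform within tolerance."""


class InsufficientDataError(ValueError):
    """Not enough data points for the requested fit."""


class DegenerateFitError(ValueError):
    """Fit is underdetermined (e.g. duplicate reference times)."""


@dataclass(frozen=True)
class RawTrace:
    """Uniformly sampled tri-axial acceleration.

    Axes follow the surge/sway/heave convention: x = fore-aft, y =
    lateral, z = dorso-ventral. At rest with the z axis up, the signal is
    approximately (0, 0, 1) g.
    """

    times: np.ndarray  # seconds from trace start, strictly increasing
    x: np.ndarray  # g
    y: np.ndarray  # g
    z: np.ndarray  # g
    rate_hz: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        for name in ("times", "x", "y", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.times) == len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("channel lengths differ")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if len(times) >= 2:
            steps = np.diff(times)
            nominal = 1.0 / self.rate_hz
            if np.any(steps <= 0):
                raise SamplingError("times not strictly increasing")
            if np.max(np.abs(steps - nominal)) > UNIFORMITY_TOL_S:
                raise SamplingError(
                    f"non-uniform sampling: max step deviation "
                    f"{np.max(np.abs(steps - nominal)):.3g} s exceeds {UNIFORMITY_TOL_S} s"
                )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def xyz(self) -> np.ndarray:
        """n×3 array of (x, y, z) samples."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass(frozen=True)
class LabelInterval:
    """A time span annotated with one behaviour under one treatment."""

    start_s: float
    end_s: float
    behaviour: str
    treatment: str

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"degenerate interval [{self.start_s}, {self.end_s})")
        validate_behaviour(self.behaviour)
        validate_treatment(self.treatment)


@dataclass(frozen=True)
class ClockModel:
    """Linear device-clock model: device = reference + offset + drift·t.

    ``offset_s`` is the device-minus-reference offset at t = 0 on the
    reference clock; ``drift_s_per_hour`` is the linear drift rate.
    """

    offset_s: float
    drift_s_per_hour: float = 0.0

    def apply(self, t):
        """Map reference-clock time(s) to device-clock time(s)."""
        t = np.asarray(t, dtype=float)
        return t + self.offset_s + self.drift_s_per_hour * (t / 3600.0)

    def invert(self, t_device):
        """Map device-clock time(s) back to reference-clock time(s)."""
        t_device = np.asarray(t_device, dtype=float)
        return (t_device - self.offset_s) / (1.0 + self.drift_s_per_hour / 3600.0)


def read_trace(path) -> RawTrace:
    """Read a trace CSV with header ``time,x,y,z`` (s, g, g, g).

    The sample rate is inferred from the median time step and the trace
    is validated for uniform sampling.
    """
    df = pd.read_csv(path)
    missing = {"time", "x", "y", "z"} - set(df.columns)
    if missing:
        raise FormatError(f"trace CSV missing columns: {sorted(missing)}")
    times = df["time"].to_numpy(dtype=float)
    if len(times) < 2:
        raise FormatError("trace needs at least 2 samples to infer a rate")
    step = float(np.median(np.diff(times)))
    if step <= 0:
        raise SamplingError("non-increasing time column")
    rate = 1.0 / step
    # snap to an integer rate when within tolerance (50 Hz written at
    # limited precision must not come back as 49.999999...)
    if abs(rate - round(rate)) < 1e-6 * rate:
        rate = float(round(rate))
    return RawTrace(
        times=times,
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        z=df["z"].to_numpy(dtype=float),
        rate_hz=rate,
    )


def write_trace(trace: RawTrace, path) -> None:
    """Write a trace to CSV (header ``time,x,y,z``), lossless to 1e-9."""
    pd.DataFrame(
        {"time": trace.times, "x": trace.x, "y": trace.y, "z": trace.z}
    ).to_csv(path, index=False, float_format="%.12g")


def read_labels(path) -> list[LabelInterval]:
    """Read label intervals from CSV with header ``start,end,behaviour,treatment``."""
    df = pd.read_csv(path)
    missing = {"start", "end", "behaviour", "treatment"} - set(df.columns)
    if missing:
        raise FormatError(f"labels CSV missing columns: {sorted(missing)}")
    return [
        LabelInterval(
            start_s=float(r.start),
            end_s=float(r.end),
            behaviour=str(r.behaviour),
            treatment=str(r.treatment),
        )
        for r in df.itertuples(index=False)
    ]


def write_labels(intervals: list[LabelInterval], path) -> None:
    pd.DataFrame(
        {
            "start": [iv.start_s for iv in intervals],
            "end": [iv.end_s for iv in intervals],
            "behaviour": [iv.behaviour for iv in intervals],
            "treatment": [iv.treatment for iv in intervals],
        }
    ).to_csv(path, index=False, float_format="%.12g")


def detect_taps(
    trace: RawTrace,
    threshold_g: float = 3.0,
    min_spikes: int = 3,
    refractory_s: float = 0.5,
) -> list[float]:
    """Detect calibration tap bursts and return their onset times.

    A sample is a spike candidate when the deviation of the acceleration
    vector norm from 1 g exceeds ``threshold_g`` (orientation-free rule).
    Candidates closer together than ``refractory_s`` merge into one
    burst; bursts with at least ``min_spikes`` candidate samples are
    reported as events, timed at their first spike.
    """
    if threshold_g <= 0:
        raise ValueError("threshold_g must be positive")
    if min_spikes < 1:
        raise ValueError("min_spikes must be >= 1")
    if len(trace) == 0:
        return []
    mag = np.abs(np.linalg.norm(trace.xyz, axis=1) - 1.0)
    cand = np.flatnonzero(mag > threshold_g)
    if cand.size == 0:
        return []
    t = trace.times[cand]
    # split where the gap between consecutive candidates exceeds the refractory
    breaks = np.flatnonzero(np.diff(t) > refractory_s)
    events: list[float] = []
    start = 0
    for stop in [*(breaks + 1), len(cand)]:
        if stop - start >= min_spikes:
            events.append(float(t[start]))
        start = stop
    return events


def fit_clock(
    device_times,
    reference_times,
    max_drift_s_per_hour: float = 5.0,
) -> ClockModel:
    """Fit the linear clock model from paired tap times.

    One pair gives a pure offset; two or more give an ordinary
    least-squares fit of (device − reference) against reference time,
    with the slope converted to seconds per hour. All pairs are weighted
    equally, including any mid-deployment calibration taps.
    """
    dev = np.asarray(device_times, dtype=float)
    ref = np.asarray(reference_times, dtype=float)
    if dev.shape != ref.shape:
        raise ValueError("device and reference time lists must pair up")
    n = dev.size
    if n == 0:
        raise InsufficientDataError("no tap pairs to fit a clock from")
    diff = dev - ref
    if n == 1:
        return ClockModel(offset_s=float(diff[0]), drift_s_per_hour=0.0)
    if np.ptp(ref) == 0:
        raise DegenerateFitError("duplicate reference times: slope undetermined")
    slope, intercept = np.polyfit(ref, diff, deg=1)
    drift = float(slope) * 3600.0
    if abs(drift) > max_drift_s_per_hour:
        raise DegenerateFitError(
            f"implausible drift {drift:.3g} s/h (bound {max_drift_s_per_hour} s/h); "
            "check tap pairing"
        )
    return ClockModel(offset_s=float(intercept), drift_s_per_hour=drift)


def align_labels(
    intervals: list[LabelInterval], clock: ClockModel
) -> list[LabelInterval]:
    """Map label interval boundaries from the reference clock to device time."""
    out = []
    for iv in intervals:
        start = float(clock.apply(iv.start_s))
        end = float(clock.apply(iv.end_s))
        if start >= end:
            raise DegenerateFitError(
                f"interval [{iv.start_s}, {iv.end_s}) degenerates under the clock model"
            )
        out.append(replace(iv, start_s=start, end_s=end))
    return out
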