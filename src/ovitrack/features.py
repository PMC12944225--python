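"""Per-window signal features for halter accelerometry.

The classifier rests on two characteristics of the gravity-free resultant
acceleration: *cumulative movement activity* (the integral of a smoothed
envelope — high during chewing of any kind, low at rest) and *high-frequency
activity* (the RMS residual after short smoothing — low for stereotyped,
regular rumination chewing, high for jerky, irregular eating).  Supporting
features are the classic signal magnitude area (SMA), the mean resultant
magnitude (MSV), and statistics of *movement breaks*, the short regular
pauses between rumination boluses.

All moving statistics use truncated windows at the trace edges (no padding),
so outputs keep the input length and constants are reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError
from .io import AccelTrace

__all__ = [
    "EnvelopeParams",
    "BreakParams",
    "FeatureParams",
    "FeatureWindow",
    "remove_gravity",
    "resultant_magnitude",
    "signal_envelope",
    "detect_movement_breaks",
    "window_features",
    "features_to_frame",
    "write_features_csv",
]

#: sentinel for break_regularity when fewer than two breaks fall in a window
REGULARITY_UNDEFINED = float("nan")


@dataclass(frozen=True)
class EnvelopeParams:
    """Envelope = moving max over ``peak_window_s`` then moving mean over
    ``smooth_window_s``.  The 1 s peak window is chosen so a single ~1 Hz chew
    cycle fills it."""

    peak_window_s: float = 1.0
    smooth_window_s: float = 2.0

    def __post_init__(self) -> None:
        if self.peak_window_s <= 0 or self.smooth_window_s <= 0:
            raise ParameterError("envelope windows must be positive")


@dataclass(frozen=True)
class BreakParams:
    """A movement break is a maximal run with envelope below ``theta_break``
    lasting at least ``min_break_s``."""

    theta_break: float = 0.05  # g
    min_break_s: float = 2.0

    def __post_init__(self) -> None:
        if self.theta_break <= 0:
            raise ParameterError("theta_break must be positive")
        if self.min_break_s <= 0:
            raise ParameterError("min_break_s must be positive")


@dataclass(frozen=True)
class FeatureParams:
    """All tunables of the feature stage, with field defaults documented in
    the methods note."""

    window_s: float = 10.0
    gravity_window_s: float = 2.5
    hf_smooth_s: float = 0.5
    envelope: EnvelopeParams = field(default_factory=EnvelopeParams)
    breaks: BreakParams = field(default_factory=BreakParams)


@dataclass
class FeatureWindow:
    """Features of one non-overlapping analysis window."""

    window_index: int
    t_start_s: float
    t_end_s: float
    sma: float  # g, mean |x|+|y|+|z| of the dynamic signal
    msv: float  # g, mean resultant magnitude
    cum_activity: float  # g·s, integral of envelope over the window
    hf_activity: float  # g, RMS residual of magnitude after short smoothing
    break_fraction: float  # fraction of the window inside movement breaks
    break_regularity: float  # CV of inter-break intervals; NaN if < 2 breaks


def _window_samples(window_s: float, rate_hz: float) -> int:
    n = int(round(window_s * rate_hz))
    return max(n, 1)


def _moving_mean(x: np.ndarray, n: int) -> np.ndarray:
    return (
        pd.Series(x).rolling(n, center=True, min_periods=1).mean().to_numpy()
    )


def _moving_max(x: np.ndarray, n: int) -> np.ndarray:
    return pd.Series(x).rolling(n, center=True, min_periods=1).max().to_numpy()


def remove_gravity(trace: AccelTrace, window_s: float = 2.5) -> AccelTrace:
    """Subtract the per-axis centred moving mean: the quasi-static
    (gravitational + postural) component.  The output is the dynamic signal.

    ``window_s`` must cover at least one sample; 2.5 s (default) spans several
    chew cycles so chewing itself is not absorbed into the gravity estimate.
    """
    if window_s <= 0:
        raise ParameterError("window_s must be positive")
    if window_s < 1.0 / trace.rate_hz:
        raise ParameterError("window_s must be at least one sample period")
    n = _window_samples(window_s, trace.rate_hz)
    return AccelTrace(
        animal_id=trace.animal_id,
        rate_hz=trace.rate_hz,
        x=trace.x - _moving_mean(trace.x, n),
        y=trace.y - _moving_mean(trace.y, n),
        z=trace.z - _moving_mean(trace.z, n),
        range_g=trace.range_g,
        start_time=trace.start_time,
    )


def resultant_magnitude(trace: AccelTrace) -> np.ndarray:
    """Orientation-free magnitude sqrt(x²+y²+z²) per sample (g).

    Meant for the dynamic (gravity-removed) trace; combining the axes into a
    resultant vector removes the influence of how the sensor sits on the
    halter.
    """
    return np.sqrt(trace.x**2 + trace.y**2 + trace.z**2)


def signal_envelope(
    m: np.ndarray,
    rate_hz: float,
    peak_window_s: float = 1.0,
    smooth_window_s: float = 2.0,
) -> np.ndarray:
    """Smoothed activity envelope: moving max then moving mean.

    Non-negative for non-negative input and never exceeds ``max(m)``.
    """
    if peak_window_s <= 0 or smooth_window_s <= 0:
        raise ParameterError("envelope windows must be positive")
    m = np.asarray(m, dtype=float)
    peaked = _moving_max(m, _window_samples(peak_window_s, rate_hz))
    return _moving_mean(peaked, _window_samples(smooth_window_s, rate_hz))


def detect_movement_breaks(
    envelope: np.ndarray,
    rate_hz: float,
    theta_break: float = 0.05,
    min_break_s: float = 2.0,
) -> list[tuple[float, float]]:
    """Maximal intervals (start_s, end_s) where the envelope stays below
    ``theta_break`` for at least ``min_break_s``.  Intervals are disjoint and
    ordered."""
    if theta_break <= 0:
        raise ParameterError("theta_break must be positive")
    if min_break_s <= 0:
        raise ParameterError("min_break_s must be positive")
    below = np.asarray(envelope) < theta_break
    if not below.any():
        return []
    edges = np.diff(below.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if below[0]:
        starts = np.concatenate([[0], starts])
    if below[-1]:
        ends = np.concatenate([ends, [below.size]])
    out = []
    for s, e in zip(starts, ends):
        if (e - s) / rate_hz >= min_break_s:
            out.append((s / rate_hz, e / rate_hz))
    return out


def _break_stats(
    breaks: list[tuple[float, float]], t0: float, t1: float
) -> tuple[float, float]:
    """(fraction of [t0, t1] inside breaks, CV of inter-break start intervals
    for breaks starting inside the window)."""
    overlap = 0.0
    starts_in = []
    for s, e in breaks:
        overlap += max(0.0, min(e, t1) - max(s, t0))
        if t0 <= s < t1:
            starts_in.append(s)
    frac = overlap / (t1 - t0)
    if len(starts_in) < 2:
        return frac, REGULARITY_UNDEFINED
    intervals = np.diff(starts_in)
    mean = intervals.mean()
    if mean == 0:
        return frac, REGULARITY_UNDEFINED
    return frac, float(intervals.std() / mean)


def window_features(
    trace: AccelTrace,
    params: FeatureParams | None = None,
) -> list[FeatureWindow]:
    """Compute all per-window features of a *raw* trace.

    Gravity is removed internally; windows are non-overlapping and anchored at
    the trace start.  ``params.window_s`` must be longer than 1 s, shorter
    than 1 min and divide 60 so that whole windows tile each minute for the
    majority vote.
    """
    params = params or FeatureParams()
    w = params.window_s
    if not (1.0 < w < 60.0):
        raise ParameterError("window_s must satisfy 1 s < window_s < 60 s")
    if abs(60.0 / w - round(60.0 / w)) > 1e-9:
        raise ParameterError("window_s must divide 60 s")
    if trace.duration_s < w:
        raise DataError("trace shorter than one analysis window")

    rate = trace.rate_hz
    dyn = remove_gravity(trace, params.gravity_window_s)
    m = resultant_magnitude(dyn)
    env = signal_envelope(
        m, rate, params.envelope.peak_window_s, params.envelope.smooth_window_s
    )
    resid = m - _moving_mean(m, _window_samples(params.hf_smooth_s, rate))
    breaks = detect_movement_breaks(
        env, rate, params.breaks.theta_break, params.breaks.min_break_s
    )
    rect = np.abs(dyn.x) + np.abs(dyn.y) + np.abs(dyn.z)

    n_per = _window_samples(w, rate)
    n_windows = len(trace) // n_per
    dt = 1.0 / rate
    out: list[FeatureWindow] = []
    for i in range(n_windows):
        sl = slice(i * n_per, (i + 1) * n_per)
        t0, t1 = i * w, (i + 1) * w
        frac, reg = _break_stats(breaks, t0, t1)
        out.append(
            FeatureWindow(
                window_index=i,
                t_start_s=t0,
                t_end_s=t1,
                sma=float(rect[sl].mean()),
                msv=float(m[sl].mean()),
                cum_activity=float(env[sl].sum() * dt),
                hf_activity=float(np.sqrt(np.mean(resid[sl] ** 2))),
                break_fraction=frac,
                break_regularity=reg,
            )
        )
    return out


def features_to_frame(windows: list[FeatureWindow]) -> pd.DataFrame:
    """Feature windows as a DataFrame in the export column order."""
    return pd.DataFrame(
        {
            "window_index": [fw.window_index for fw in windows],
            "t_start_s": [fw.t_start_s for fw in windows],
            "t_end_s": [fw.t_end_s for fw in windows],
            "sma": [fw.sma for fw in windows],
            "msv": [fw.msv for fw in windows],
            "cum_activity": [fw.cum_activity for fw in windows],
            "hf_activity": [fw.hf_activity for fw in windows],
            "break_fraction": [fw.break_fraction for fw in windows],
            "break_regularity": [fw.break_regularity for fw in windows],
        }
    )


def write_features_csv(windows: list[FeatureWindow], path: str | Path) -> None:
    features_to_frame(windows).to_csv(path, index=False, float_format="%.6f")
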