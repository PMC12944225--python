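"""Domain types and CSV I/O for halter-accelerometer traces and behaviour logs.

The sensor streams triaxial acceleration at a nominal 10 Hz with a ±2 g
measurement range; behaviour annotations come from human observers who log a
behaviour change with a one-second timestamp, so an annotation holds until the
next one.  Behaviour is evaluated at one-minute resolution: the per-second log
is reduced to one label per complete minute by taking the modal behaviour.

All timestamps are seconds relative to the start of the recording.  CSV
dialects::

    trace:      time_s,x_g,y_g,z_g           one row per sample
    annotation: time_s,behaviour[,posture]   one row per change-point
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError

__all__ = [
    "BehaviourLabel",
    "Posture",
    "LabelSource",
    "AccelTrace",
    "AnnotationSeries",
    "MinuteLabelSeries",
    "read_accel_csv",
    "write_accel_csv",
    "read_annotations",
    "write_annotations",
    "annotations_to_minutes",
    "write_minutes_csv",
    "read_minutes_csv",
    "posture_minutes",
    "minute_mode",
    "DEFAULT_TIE_PRIORITY",
]


class BehaviourLabel(IntEnum):
    """The four analysis classes.  OTHER absorbs drinking, walking and MISC.

    Integer codes double as the default tie-break priority (lower wins), so
    ``RUMINATION > EATING > RESTING_IDLING > OTHER`` favours the
    welfare-relevant active behaviours.
    """

    RUMINATION = 0
    EATING = 1
    RESTING_IDLING = 2
    OTHER = 3


class Posture(IntEnum):
    STANDING = 0
    LYING = 1
    UNKNOWN = 2


class LabelSource(IntEnum):
    OBSERVED = 0
    PREDICTED = 1


DEFAULT_TIE_PRIORITY: tuple[BehaviourLabel, ...] = (
    BehaviourLabel.RUMINATION,
    BehaviourLabel.EATING,
    BehaviourLabel.RESTING_IDLING,
    BehaviourLabel.OTHER,
)

# observer-app vocabulary -> analysis class
_BEHAVIOUR_TOKENS = {
    "eating": BehaviourLabel.EATING,
    "ruminating": BehaviourLabel.RUMINATION,
    "rumination": BehaviourLabel.RUMINATION,
    "resting/idling": BehaviourLabel.RESTING_IDLING,
    "resting_idling": BehaviourLabel.RESTING_IDLING,
    "resting": BehaviourLabel.RESTING_IDLING,
    "idling": BehaviourLabel.RESTING_IDLING,
    "drinking": BehaviourLabel.OTHER,
    "walking": BehaviourLabel.OTHER,
    "other": BehaviourLabel.OTHER,
    "other (misc)": BehaviourLabel.OTHER,
    "other/misc": BehaviourLabel.OTHER,
    "misc": BehaviourLabel.OTHER,
}

_BEHAVIOUR_NAMES = {
    BehaviourLabel.EATING: "eating",
    BehaviourLabel.RUMINATION: "ruminating",
    BehaviourLabel.RESTING_IDLING: "resting/idling",
    BehaviourLabel.OTHER: "other",
}

_POSTURE_TOKENS = {
    "standing": Posture.STANDING,
    "lying": Posture.LYING,
    "unknown": Posture.UNKNOWN,
}


@dataclass
class AccelTrace:
    """A triaxial acceleration record at a fixed sampling rate.

    ``x``, ``y``, ``z`` are equal-length arrays in g.  ``range_g`` is the
    sensor's saturation range; samples are clipped to it on read (the hardware
    itself saturates), with the clip count kept in ``n_clipped``.  Gravity
    removal may push derived (dynamic) traces slightly outside the range, so
    the bound is enforced at the I/O boundary, not here.
    """

    animal_id: str
    rate_hz: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    range_g: float = 2.0
    start_time: float = 0.0
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise DataError("x, y, z must have equal length")
        if len(self.x) < 1:
            raise DataError("trace must contain at least one sample")
        if self.rate_hz <= 0:
            raise DataError("rate_hz must be positive")
        if self.range_g <= 0:
            raise DataError("range_g must be positive")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return len(self.x) / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.x)) / self.rate_hz

    def as_array(self) -> np.ndarray:
        """(n, 3) array of samples."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass
class AnnotationSeries:
    """Behaviour (and optional posture) at one-second resolution."""

    animal_id: str
    labels: np.ndarray  # int8 codes of BehaviourLabel, one per second
    posture: np.ndarray | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.size == 0:
            raise DataError("annotation series must be non-empty")
        if self.posture is not None:
            self.posture = np.asarray(self.posture, dtype=np.int8)
            if self.posture.shape != self.labels.shape:
                raise DataError("posture must have the same length as labels")

    @property
    def duration_s(self) -> int:
        return int(self.labels.size)


@dataclass
class MinuteLabelSeries:
    """One behaviour label per whole minute — the unit of evaluation."""

    animal_id: str
    labels: np.ndarray  # int8 codes, one per minute
    source: LabelSource = LabelSource.OBSERVED
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.size == 0:
            raise DataError("minute label series must be non-empty")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_minutes(self) -> int:
        return int(self.labels.size)


def read_accel_csv(
    path: str | Path,
    rate_hz: float = 10.0,
    range_g: float = 2.0,
    animal_id: str = "",
) -> AccelTrace:
    """Read a trace CSV (``time_s,x_g,y_g,z_g``).

    Values outside ±``range_g`` are clipped to the range — the ADXL-class
    sensor saturates rather than errors — and counted in the returned trace's
    ``n_clipped`` (a warning is also emitted).

    Raises
    ------
    FormatError
        if a required column is missing.
    DataError
        if the file is empty or time is not strictly increasing.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty trace file") from None
    required = ["time_s", "x_g", "y_g", "z_g"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise DataError(f"{path}: no samples")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise DataError(f"{path}: time_s must be strictly increasing")
    xyz = df[["x_g", "y_g", "z_g"]].to_numpy(dtype=float)
    n_clipped = int(np.count_nonzero(np.abs(xyz) > range_g))
    if n_clipped:
        warnings.warn(
            f"{path}: {n_clipped} sample(s) outside ±{range_g} g clipped",
            stacklevel=2,
        )
        xyz = np.clip(xyz, -range_g, range_g)
    return AccelTrace(
        animal_id=animal_id,
        rate_hz=rate_hz,
        x=xyz[:, 0],
        y=xyz[:, 1],
        z=xyz[:, 2],
        range_g=range_g,
        start_time=float(t[0]),
        n_clipped=n_clipped,
    )


def write_accel_csv(trace: AccelTrace, path: str | Path) -> None:
    """Write a trace in the ``time_s,x_g,y_g,z_g`` dialect (6 decimals)."""
    df = pd.DataFrame(
        {
            "time_s": trace.times,
            "x_g": trace.x,
            "y_g": trace.y,
            "z_g": trace.z,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def _parse_behaviour(token: str) -> tuple[int, bool]:
    label = _BEHAVIOUR_TOKENS.get(str(token).strip().lower())
    if label is None:
        return int(BehaviourLabel.OTHER), True
    return int(label), False


def read_annotations(
    path: str | Path,
    duration_s: int | None = None,
    animal_id: str = "",
) -> AnnotationSeries:
    """Read an annotation CSV (``time_s,behaviour[,posture]``) into a
    1 s-resolution series.

    Each row is a change-point: its behaviour holds until the next row
    (forward fill).  ``duration_s`` sets the series end; by default the last
    annotation is held for 60 s.  Unknown behaviour tokens map to OTHER with a
    warning.  Duplicate timestamps are reduced deterministically (highest
    priority label wins) so results do not depend on row order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty annotation file") from None
    if "time_s" not in df.columns or "behaviour" not in df.columns:
        raise FormatError(f"{path}: need columns time_s,behaviour")
    if len(df) == 0:
        raise DataError(f"{path}: no annotations")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise DataError(f"{path}: time_s must be non-decreasing")

    codes = np.empty(len(df), dtype=np.int8)
    n_unknown = 0
    for i, tok in enumerate(df["behaviour"]):
        codes[i], unknown = _parse_behaviour(tok)
        n_unknown += unknown
    if n_unknown:
        warnings.warn(
            f"{path}: {n_unknown} unrecognised behaviour token(s) mapped to OTHER",
            stacklevel=2,
        )

    has_posture = "posture" in df.columns
    if has_posture:
        pcodes = np.array(
            [
                int(_POSTURE_TOKENS.get(str(tok).strip().lower(), Posture.UNKNOWN))
                for tok in df["posture"]
            ],
            dtype=np.int8,
        )
    else:
        pcodes = None

    # dedup equal timestamps: keep the highest-priority (lowest-code) label,
    # which is invariant to input row order
    order = np.lexsort((codes, t))
    t, codes = t[order], codes[order]
    if pcodes is not None:
        pcodes = pcodes[order]
    keep = np.concatenate([[True], np.diff(t) > 0])
    t, codes = t[keep], codes[keep]
    if pcodes is not None:
        pcodes = pcodes[keep]

    t0 = int(np.floor(t[0]))
    if duration_s is None:
        end = int(np.floor(t[-1])) + 60
    else:
        end = t0 + int(duration_s)
    n = end - t0
    if n < 1:
        raise DataError(f"{path}: duration shorter than one second")
    seconds = t0 + np.arange(n)
    idx = np.searchsorted(t, seconds, side="right") - 1
    idx = np.clip(idx, 0, len(t) - 1)
    labels = codes[idx]
    posture = pcodes[idx] if pcodes is not None else None
    return AnnotationSeries(
        animal_id=animal_id, labels=labels, posture=posture, start_time=float(t0)
    )


def write_annotations(a: AnnotationSeries, path: str | Path) -> None:
    """Write change-points of a 1 s series in the annotation dialect."""
    labels = a.labels
    change = np.concatenate([[True], np.diff(labels) != 0])
    if a.posture is not None:
        change |= np.concatenate([[True], np.diff(a.posture) != 0])
    times = a.start_time + np.flatnonzero(change)
    out = {
        "time_s": times.astype(int),
        "behaviour": [_BEHAVIOUR_NAMES[BehaviourLabel(c)] for c in labels[change]],
    }
    if a.posture is not None:
        out["posture"] = [Posture(p).name.lower() for p in a.posture[change]]
    pd.DataFrame(out).to_csv(path, index=False)


def minute_mode(
    labels: np.ndarray,
    tie_priority: Sequence[BehaviourLabel] = DEFAULT_TIE_PRIORITY,
) -> np.ndarray:
    """Modal label of each 60-entry block; ties broken by ``tie_priority``.

    ``labels`` must have length a multiple of 60.
    """
    labels = np.asarray(labels, dtype=np.int8)
    if labels.size % 60 != 0:
        raise DataError("label length must be a multiple of 60")
    n_min = labels.size // 60
    blocks = labels.reshape(n_min, 60)
    counts = (blocks[:, :, None] == np.arange(4, dtype=np.int8)).sum(axis=1)
    # rank matrix: higher count wins, then earlier position in tie_priority
    rank = np.array([list(tie_priority).index(BehaviourLabel(c)) for c in range(4)])
    keyed = counts * 10 - rank  # counts ≤ 60 so scale 10 > max rank spread
    return np.argmax(keyed, axis=1).astype(np.int8)


def annotations_to_minutes(
    a: AnnotationSeries,
    tie_priority: Sequence[BehaviourLabel] = DEFAULT_TIE_PRIORITY,
) -> MinuteLabelSeries:
    """Reduce a 1 s annotation series to one modal label per complete minute.

    Trailing partial minutes are dropped.  Raises :class:`DataError` if the
    series is shorter than one minute.
    """
    n_min = a.labels.size // 60
    if n_min < 1:
        raise DataError("annotation series shorter than one minute")
    labels = minute_mode(a.labels[: n_min * 60], tie_priority)
    return MinuteLabelSeries(
        animal_id=a.animal_id,
        labels=labels,
        source=LabelSource.OBSERVED,
        start_time=a.start_time,
    )


def write_minutes_csv(m: MinuteLabelSeries, path: str | Path) -> None:
    """Write a minute-label series (``minute,behaviour`` dialect)."""
    pd.DataFrame(
        {
            "minute": np.arange(m.n_minutes),
            "behaviour": [_BEHAVIOUR_NAMES[BehaviourLabel(c)] for c in m.labels],
        }
    ).to_csv(path, index=False)


def read_minutes_csv(
    path: str | Path,
    source: LabelSource = LabelSource.PREDICTED,
    animal_id: str = "",
) -> MinuteLabelSeries:
    """Read a ``minute,behaviour`` CSV back into a minute-label series."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty minute-label file") from None
    if "behaviour" not in df.columns:
        raise FormatError(f"{path}: need a behaviour column")
    if len(df) == 0:
        raise DataError(f"{path}: no minutes")
    labels = np.array([_parse_behaviour(tok)[0] for tok in df["behaviour"]], np.int8)
    return MinuteLabelSeries(animal_id=animal_id, labels=labels, source=source)


def posture_minutes(a: AnnotationSeries) -> np.ndarray:
    """Modal posture per complete minute (UNKNOWN only if the whole minute is).

    Returns int8 codes of :class:`Posture`; requires the series to carry
    posture.
    """
    if a.posture is None:
        raise DataError("annotation series has no posture channel")
    n_min = a.posture.size // 60
    if n_min < 1:
        raise DataError("annotation series shorter than one minute")
    blocks = a.posture[: n_min * 60].reshape(n_min, 60)
    counts = (blocks[:, :, None] == np.arange(3, dtype=np.int8)).sum(axis=1)
    known = counts[:, :2]
    out = np.where(
        known.sum(axis=1) > 0,
        np.argmax(known, axis=1),
        int(Posture.UNKNOWN),
    )
    return out.astype(np.int8)
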