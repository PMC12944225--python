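"""Seeded synthetic data: behaviour schedules, accelerometer traces and
duration tables.

The generator states a simple phenomenology of the three target behaviours as
seen by a cheek-mounted 10 Hz, ±2 g sensor:

* **Rumination** — rotary chewing at ~1.2 Hz in long bouts (~50 s, one bolus)
  separated by short, near-regular swallowing pauses (~5 s).  Chew strokes
  are modelled as elliptical motion in the plane orthogonal to gravity, which
  keeps the resultant magnitude steady during a bout: the "regular chewing,
  low high-frequency noise" signature.
* **Eating** — irregular bursts of larger, jerkier head/jaw motion (random
  burst direction, broadband jerk noise, occasional large transients) with
  variable gaps: high cumulative activity *and* high high-frequency noise.
* **Resting/idling** — low white noise with sparse posture-shift spikes.

Gravity (1 g) rides on a configurable orientation axis; everything clips at
±range_g like the real sensor.  The emitted annotation series matches the
schedule second-for-second, so every downstream stage can be scored against
exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import AccelTrace, AnnotationSeries, BehaviourLabel, Posture

__all__ = [
    "RuminationParams",
    "EatingParams",
    "RestingParams",
    "SimConfig",
    "BehaviourSchedule",
    "simulate_schedule",
    "synth_trace",
    "synth_duration_table",
    "TABLE_BASELINE_MEANS",
    "TABLE_BASELINE_SDS",
    "TABLE_UNFAMILIAR_SDS",
    "TABLE_STRESS_MULTIPLIERS",
]


@dataclass(frozen=True)
class RuminationParams:
    chew_hz: float = 1.2
    chew_amp_g: float = 0.25
    ellipticity: float = 0.6  # minor/major axis of the rotary chew stroke
    bout_s: float = 50.0  # one bolus of chewing
    pause_s: float = 5.0  # swallow/regurgitate pause between boluses
    pause_jitter_cv: float = 0.05


@dataclass(frozen=True)
class EatingParams:
    burst_hz: float = 2.5
    amp_g: float = 0.45
    burst_len_s: float = 12.0
    gap_s: float = 4.0
    transient_rate_per_min: float = 6.0
    transient_amp_g: float = 1.0
    jerk_sd_g: float = 0.15


@dataclass(frozen=True)
class RestingParams:
    noise_sd_g: float = 0.02
    shift_rate_per_min: float = 0.2
    shift_amp_g: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    """All generator tunables; defaults are the stated world of the tests."""

    seed: int = 0
    rate_hz: float = 10.0
    range_g: float = 2.0
    sensor_noise_sd_g: float = 0.01
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rumination: RuminationParams = field(default_factory=RuminationParams)
    eating: EatingParams = field(default_factory=EatingParams)
    resting: RestingParams = field(default_factory=RestingParams)

    def __post_init__(self) -> None:
        if self.rate_hz <= 0 or self.range_g <= 0:
            raise ParameterError("rate_hz and range_g must be positive")
        o = np.asarray(self.orientation, dtype=float)
        norm = np.linalg.norm(o)
        if norm == 0:
            raise ParameterError("orientation must be a non-zero vector")
        object.__setattr__(self, "orientation", tuple(o / norm))
        if (
            self.rumination.chew_amp_g < 0
            or self.eating.amp_g < 0
            or self.resting.noise_sd_g < 0
        ):
            raise ParameterError("amplitudes must be non-negative")


@dataclass
class BehaviourSchedule:
    """Ordered behaviour bouts: (behaviour, duration in whole seconds)."""

    segments: list[tuple[BehaviourLabel, int]]

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.segments):
            raise ParameterError("segment durations must be positive")
        if self.total_s < 60:
            raise ParameterError("schedule must cover at least one minute")

    @property
    def total_s(self) -> int:
        return int(sum(d for _, d in self.segments))

    def labels_per_second(self) -> np.ndarray:
        return np.concatenate(
            [np.full(d, int(b), dtype=np.int8) for b, d in self.segments]
        )

    def time_share(self) -> dict[BehaviourLabel, float]:
        total = self.total_s
        share: dict[BehaviourLabel, float] = {}
        for b, d in self.segments:
            share[b] = share.get(b, 0.0) + d / total
        return share


DEFAULT_MEAN_BOUT_MIN = {
    BehaviourLabel.RUMINATION: 25.0,
    BehaviourLabel.RESTING_IDLING: 25.0,
    BehaviourLabel.EATING: 12.0,
    BehaviourLabel.OTHER: 4.0,
}


def simulate_schedule(
    total_min: float,
    quotas: dict[BehaviourLabel, float],
    mean_bout_min: dict[BehaviourLabel, float] | None = None,
    seed: int = 0,
) -> BehaviourSchedule:
    """Alternating behaviour bouts filling ``total_min`` minutes.

    Bout lengths are exponential (mean ``mean_bout_min``, floored at 1 min)
    and capped at each behaviour's remaining time budget, so realised time
    shares match ``quotas`` exactly up to the 1 s rounding of budgets.
    Reproducible by ``seed``.
    """
    if total_min < 1:
        raise ParameterError("total_min must be at least 1")
    qsum = sum(quotas.values())
    if abs(qsum - 1.0) > 1e-6:
        raise ParameterError(f"quotas must sum to 1 (got {qsum})")
    mean_bout_min = mean_bout_min or DEFAULT_MEAN_BOUT_MIN
    total_s = int(round(total_min * 60))
    behaviours = [b for b, q in quotas.items() if q > 0]
    remaining = {b: int(round(quotas[b] * total_s)) for b in behaviours}
    # absorb rounding drift in the largest budget
    drift = total_s - sum(remaining.values())
    remaining[max(behaviours, key=lambda b: remaining[b])] += drift

    rng = np.random.default_rng(seed)
    segments: list[tuple[BehaviourLabel, int]] = []
    prev: BehaviourLabel | None = None
    while any(r > 0 for r in remaining.values()):
        cands = [b for b in behaviours if remaining[b] > 0]
        if len(cands) > 1 and prev in cands:
            cands = [b for b in cands if b != prev]
        weights = np.array([remaining[b] for b in cands], dtype=float)
        b = cands[rng.choice(len(cands), p=weights / weights.sum())]
        mean_s = mean_bout_min.get(b, 10.0) * 60.0
        bout = int(round(max(60.0, rng.exponential(mean_s))))
        bout = min(bout, remaining[b])
        remaining[b] -= bout
        if bout > 0:
            segments.append((b, bout))
            prev = b
    return BehaviourSchedule(segments=segments)


def _orthonormal_basis(o: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to ``o``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(o @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(o, helper)
    u /= np.linalg.norm(u)
    v = np.cross(o, u)
    return u, v


def _rumination_segment(
    n: int, rate: float, p: RuminationParams, basis, rng: np.random.Generator
) -> np.ndarray:
    u, v = basis
    out = np.zeros((n, 3))
    t = np.arange(n) / rate
    phase = 2 * np.pi * p.chew_hz * t + rng.uniform(0, 2 * np.pi)
    pos = 0
    while pos < n:
        amp = p.chew_amp_g * (1.0 + 0.05 * rng.standard_normal())
        bout_n = int(round(p.bout_s * rate))
        end = min(pos + bout_n, n)
        sl = slice(pos, end)
        out[sl] = np.outer(amp * np.sin(phase[sl]), u) + np.outer(
            p.ellipticity * amp * np.cos(phase[sl]), v
        )
        pause = p.pause_s * max(
            0.2, 1.0 + p.pause_jitter_cv * rng.standard_normal()
        )
        pos = end + int(round(pause * rate))
    return out


def _eating_segment(
    n: int, rate: float, p: EatingParams, rng: np.random.Generator
) -> np.ndarray:
    out = np.zeros((n, 3))
    t = np.arange(n) / rate
    pos = 0
    while pos < n:
        burst_n = int(round(np.clip(rng.exponential(p.burst_len_s), 2.0, 40.0) * rate))
        end = min(pos + burst_n, n)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        amp = p.amp_g * rng.lognormal(0.0, 0.25)
        phase = 2 * np.pi * p.burst_hz * t[pos:end] + rng.uniform(0, 2 * np.pi)
        out[pos:end] = np.outer(amp * np.sin(phase), direction)
        out[pos:end] += rng.normal(0.0, p.jerk_sd_g, (end - pos, 3))
        pos = end + int(round(np.clip(rng.exponential(p.gap_s), 1.0, 20.0) * rate))
    # large transients: trough competition, head throws
    n_tr = rng.poisson(p.transient_rate_per_min * n / rate / 60.0)
    for _ in range(n_tr):
        start = rng.integers(0, n)
        length = max(2, int(round(0.3 * rate)))
        end = min(start + length, n)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        shape = np.sin(np.linspace(0, np.pi, end - start))
        out[start:end] += np.outer(
            p.transient_amp_g * (0.5 + rng.random()) * shape, direction
        )
    return out


def _resting_segment(
    n: int, rate: float, p: RestingParams, rng: np.random.Generator
) -> np.ndarray:
    out = rng.normal(0.0, p.noise_sd_g, (n, 3))
    n_shift = rng.poisson(p.shift_rate_per_min * n / rate / 60.0)
    for _ in range(n_shift):
        start = rng.integers(0, n)
        length = max(2, int(round(1.0 * rate)))
        end = min(start + length, n)
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        shape = np.sin(np.linspace(0, np.pi, end - start))
        out[start:end] += np.outer(p.shift_amp_g * shape, direction)
    return out


def synth_trace(
    schedule: BehaviourSchedule,
    cfg: SimConfig | None = None,
    animal_id: str = "synthetic",
) -> tuple[AccelTrace, AnnotationSeries]:
    """Render a schedule into a raw trace plus its exact annotation series.

    Posture is emitted too: eating and OTHER are standing; rumination and
    resting bouts are lying with probability 0.6 (drawn per bout).
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.rate_hz
    o = np.asarray(cfg.orientation)
    basis = _orthonormal_basis(o)

    chunks = []
    posture_chunks = []
    for behaviour, dur_s in schedule.segments:
        n = int(round(dur_s * rate))
        if behaviour == BehaviourLabel.RUMINATION:
            dyn = _rumination_segment(n, rate, cfg.rumination, basis, rng)
            lying = rng.random() < 0.6
        elif behaviour == BehaviourLabel.EATING:
            dyn = _eating_segment(n, rate, cfg.eating, rng)
            lying = False
        elif behaviour == BehaviourLabel.RESTING_IDLING:
            dyn = _resting_segment(n, rate, cfg.resting, rng)
            lying = rng.random() < 0.6
        else:  # OTHER: moderate unstructured motion (walking, drinking, ...)
            dyn = rng.normal(0.0, 0.08, (n, 3))
            lying = False
        chunks.append(dyn)
        posture_chunks.append(
            np.full(dur_s, int(Posture.LYING if lying else Posture.STANDING), np.int8)
        )

    dyn = np.vstack(chunks)
    dyn += rng.normal(0.0, cfg.sensor_noise_sd_g, dyn.shape)
    samples = dyn + o[None, :]
    samples = np.clip(samples, -cfg.range_g, cfg.range_g)
    trace = AccelTrace(
        animal_id=animal_id,
        rate_hz=rate,
        x=samples[:, 0],
        y=samples[:, 1],
        z=samples[:, 2],
        range_g=cfg.range_g,
    )
    annotations = AnnotationSeries(
        animal_id=animal_id,
        labels=schedule.labels_per_second(),
        posture=np.concatenate(posture_chunks),
    )
    return trace, annotations


# Published field-study daily budgets (min/24 h) used as generator defaults:
# baseline means/SDs of the three target behaviours and the multiplicative
# effect of the unfamiliar condition on each mean.
TABLE_BASELINE_MEANS = {
    BehaviourLabel.RUMINATION: 485.5,
    BehaviourLabel.RESTING_IDLING: 637.0,
    BehaviourLabel.EATING: 267.5,
}
TABLE_BASELINE_SDS = {
    BehaviourLabel.RUMINATION: 38.7,
    BehaviourLabel.RESTING_IDLING: 40.6,
    BehaviourLabel.EATING: 58.7,
}
TABLE_UNFAMILIAR_SDS = {
    BehaviourLabel.RUMINATION: 54.6,
    BehaviourLabel.RESTING_IDLING: 86.9,
    BehaviourLabel.EATING: 18.4,
}
TABLE_STRESS_MULTIPLIERS = {
    BehaviourLabel.RUMINATION: 0.544,
    BehaviourLabel.RESTING_IDLING: 1.479,
    BehaviourLabel.EATING: 0.638,
}

_BEHAVIOUR_NAMES = {
    BehaviourLabel.RUMINATION: "rumination",
    BehaviourLabel.RESTING_IDLING: "resting_idling",
    BehaviourLabel.EATING: "eating",
}


def synth_duration_table(
    n_animals: int = 4,
    baseline_means: dict[BehaviourLabel, float] | None = None,
    baseline_sds: dict[BehaviourLabel, float] | None = None,
    stress_multipliers: dict[BehaviourLabel, float] | None = None,
    unfamiliar_sds: dict[BehaviourLabel, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian per-animal daily budgets for both conditions.

    Draws are truncated at 0; the OTHER category absorbs the remainder so each
    animal-condition day sums to exactly 1440 min (if the three draws exceed
    1440 they are rescaled proportionally and OTHER is 0).  Defaults
    parameterise the published baseline budgets and stress effects.
    """
    baseline_means = baseline_means or TABLE_BASELINE_MEANS
    baseline_sds = baseline_sds or TABLE_BASELINE_SDS
    stress_multipliers = stress_multipliers or TABLE_STRESS_MULTIPLIERS
    unfamiliar_sds = unfamiliar_sds or TABLE_UNFAMILIAR_SDS
    behaviours = list(baseline_means)
    for cond_means in (
        baseline_means,
        {b: baseline_means[b] * stress_multipliers.get(b, 1.0) for b in behaviours},
    ):
        if sum(cond_means.values()) > 1440:
            raise ParameterError("configured means exceed 1440 min/24 h")

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(1, n_animals + 1):
        animal = str(i)
        for condition in ("baseline", "unfamiliar"):
            draws = {}
            for b in behaviours:
                if condition == "baseline":
                    mu, sd = baseline_means[b], baseline_sds[b]
                else:
                    mu = baseline_means[b] * stress_multipliers.get(b, 1.0)
                    sd = unfamiliar_sds.get(b, baseline_sds[b])
                val = rng.normal(mu, sd)
                while val < 0:
                    val = rng.normal(mu, sd)
                draws[b] = val
            total = sum(draws.values())
            if total > 1440:
                draws = {b: v * 1440.0 / total for b, v in draws.items()}
            minutes = {b: int(round(v)) for b, v in draws.items()}
            other = 1440 - sum(minutes.values())
            while other < 0:  # rounding pushed the total past a full day
                largest = max(minutes, key=minutes.get)
                minutes[largest] -= 1
                other += 1
            for b in behaviours:
                rows.append(
                    (animal, condition, _BEHAVIOUR_NAMES[b], "any", minutes[b])
                )
            rows.append((animal, condition, "other", "any", other))
    return pd.DataFrame(
        rows, columns=["animal", "condition", "behaviour", "posture", "minutes"]
    )
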