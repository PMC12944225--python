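"""Threshold behaviour classifier with grid calibration and majority voting.

The decision rule mirrors how the three target behaviours separate in the
(cumulative activity, high-frequency activity) plane:

* low cumulative movement activity            -> resting/idling
* high cumulative, low high-frequency noise   -> rumination
  (regular, stereotyped chewing)
* high cumulative, high high-frequency noise  -> eating
  (irregular, jerky head and jaw motion)

Window decisions are aggregated to one label per minute by majority vote; the
minute is the unit of evaluation.  Calibration is a deterministic grid search
over the two thresholds maximising the mean one-vs-rest Cohen's kappa against
minute-level gold-standard labels, exposed both as a plain function
(:func:`calibrate`) and as a Model/Results pair
(:class:`ThresholdBehaviourModel`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import CalibrationError, DataError, ParameterError
from .features import (
    BreakParams,
    EnvelopeParams,
    FeatureParams,
    FeatureWindow,
    features_to_frame,
    window_features,
)
from .io import (
    DEFAULT_TIE_PRIORITY,
    AccelTrace,
    BehaviourLabel,
    LabelSource,
    MinuteLabelSeries,
)

__all__ = [
    "ClassifierConfig",
    "WindowDecision",
    "classify_window",
    "classify_trace",
    "calibrate",
    "ThresholdBehaviourModel",
    "ThresholdBehaviourResults",
]

TARGET_CLASSES = (
    BehaviourLabel.RUMINATION,
    BehaviourLabel.EATING,
    BehaviourLabel.RESTING_IDLING,
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision thresholds plus the feature parameters they were tuned for.

    ``theta_low`` (g·s) splits resting from active windows on cumulative
    activity; ``theta_noise`` (g) splits rumination from eating on
    high-frequency activity.
    """

    theta_low: float
    theta_noise: float
    features: FeatureParams = field(default_factory=FeatureParams)

    def __post_init__(self) -> None:
        if self.theta_low <= 0:
            raise ParameterError("theta_low must be positive")
        if self.theta_noise <= 0:
            raise ParameterError("theta_noise must be positive")

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "theta_low": float(self.theta_low),
            "theta_noise": float(self.theta_noise),
            "window_s": float(self.features.window_s),
            "gravity_window_s": float(self.features.gravity_window_s),
            "hf_smooth_s": float(self.features.hf_smooth_s),
            "envelope_peak_window_s": float(self.features.envelope.peak_window_s),
            "envelope_smooth_window_s": float(self.features.envelope.smooth_window_s),
            "break_theta": float(self.features.breaks.theta_break),
            "break_min_s": float(self.features.breaks.min_break_s),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassifierConfig":
        data = yaml.safe_load(Path(path).read_text())
        fp = FeatureParams(
            window_s=data.get("window_s", 10.0),
            gravity_window_s=data.get("gravity_window_s", 2.5),
            hf_smooth_s=data.get("hf_smooth_s", 0.5),
            envelope=EnvelopeParams(
                peak_window_s=data.get("envelope_peak_window_s", 1.0),
                smooth_window_s=data.get("envelope_smooth_window_s", 2.0),
            ),
            breaks=BreakParams(
                theta_break=data.get("break_theta", 0.05),
                min_break_s=data.get("break_min_s", 2.0),
            ),
        )
        return cls(
            theta_low=data["theta_low"],
            theta_noise=data["theta_noise"],
            features=fp,
        )


@dataclass
class WindowDecision:
    """Label of one analysis window with the normalised distance to the
    deciding thresholds (used for minute-level tie-breaking)."""

    window_index: int
    label: BehaviourLabel
    margin: float


def _decide(cum: np.ndarray, hf: np.ndarray, cfg: ClassifierConfig):
    """Vectorised decision rule; returns (labels int8, margins float)."""
    cum = np.asarray(cum, dtype=float)
    hf = np.asarray(hf, dtype=float)
    labels = np.where(
        cum < cfg.theta_low,
        np.int8(BehaviourLabel.RESTING_IDLING),
        np.where(
            hf < cfg.theta_noise,
            np.int8(BehaviourLabel.RUMINATION),
            np.int8(BehaviourLabel.EATING),
        ),
    ).astype(np.int8)
    margins = np.minimum(
        np.abs(cum - cfg.theta_low) / cfg.theta_low,
        np.abs(hf - cfg.theta_noise) / cfg.theta_noise,
    )
    return labels, margins


def classify_window(fw: FeatureWindow, cfg: ClassifierConfig) -> WindowDecision:
    """Apply the two-threshold rule to a single feature window."""
    labels, margins = _decide([fw.cum_activity], [fw.hf_activity], cfg)
    return WindowDecision(
        window_index=fw.window_index,
        label=BehaviourLabel(int(labels[0])),
        margin=float(margins[0]),
    )


def majority_vote(
    labels: np.ndarray,
    margins: np.ndarray,
    windows_per_minute: int,
    tie_priority: Sequence[BehaviourLabel] = DEFAULT_TIE_PRIORITY,
) -> np.ndarray:
    """Minute labels from window labels by majority vote.

    Ties on the vote count are broken by the largest summed margin among the
    tied classes, then by ``tie_priority``.  ``labels`` length must be a
    multiple of ``windows_per_minute``.
    """
    labels = np.asarray(labels, dtype=np.int8)
    margins = np.asarray(margins, dtype=float)
    if labels.size % windows_per_minute != 0:
        raise DataError("window count not a multiple of windows per minute")
    n_min = labels.size // windows_per_minute
    blocks = labels.reshape(n_min, windows_per_minute)
    mblocks = margins.reshape(n_min, windows_per_minute)
    onehot = blocks[:, :, None] == np.arange(4, dtype=np.int8)
    counts = onehot.sum(axis=1)
    margin_sums = (onehot * mblocks[:, :, None]).sum(axis=1)
    rank = np.array([list(tie_priority).index(BehaviourLabel(c)) for c in range(4)])
    # lexicographic key: count, then summed margin, then priority
    best = counts == counts.max(axis=1, keepdims=True)
    masked_margin = np.where(best, margin_sums, -np.inf)
    best &= masked_margin == masked_margin.max(axis=1, keepdims=True)
    keyed = np.where(best, -rank, -np.inf)
    return np.argmax(keyed, axis=1).astype(np.int8)


def classify_trace(
    trace: AccelTrace,
    cfg: ClassifierConfig,
    animal_id: str | None = None,
) -> MinuteLabelSeries:
    """Classify a raw trace into one predicted behaviour per complete minute."""
    if trace.duration_s < 60.0:
        raise DataError("trace must cover at least one minute")
    windows = window_features(trace, cfg.features)
    frame = features_to_frame(windows)
    labels, margins = _decide(
        frame["cum_activity"].to_numpy(), frame["hf_activity"].to_numpy(), cfg
    )
    wpm = int(round(60.0 / cfg.features.window_s))
    n_min = labels.size // wpm
    minute_labels = majority_vote(labels[: n_min * wpm], margins[: n_min * wpm], wpm)
    return MinuteLabelSeries(
        animal_id=animal_id if animal_id is not None else trace.animal_id,
        labels=minute_labels,
        source=LabelSource.PREDICTED,
        start_time=trace.start_time,
    )


def _one_vs_rest_kappa(truth: np.ndarray, pred: np.ndarray, cls: int) -> float:
    """Binary Cohen's kappa for one class (NaN if chance agreement is 1)."""
    t = truth == cls
    p = pred == cls
    n = t.size
    tp = int(np.sum(t & p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    po = (tp + tn) / n
    pc = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    if pc >= 1.0:
        return float("nan")
    return (po - pc) / (1 - pc)


class ThresholdBehaviourModel:
    """Grid calibration of the two-threshold classifier against gold labels.

    Parameters
    ----------
    features
        Feature windows (as returned by :func:`ovitrack.features.window_features`
        or their DataFrame form) computed with ``feature_params``.
    truth
        Minute-level gold-standard labels covering the feature windows.
    theta_low_grid, theta_noise_grid
        Candidate thresholds.  By default 25 values spanning the inner
        quantile range of the respective feature, which keeps the scan
        deterministic for a given dataset.

    ``fit()`` scans theta_low (outer, ascending) × theta_noise (inner,
    ascending) and keeps the first maximum of the mean one-vs-rest kappa over
    the three target classes, so repeated runs give identical configurations.
    """

    def __init__(
        self,
        features: list[FeatureWindow] | pd.DataFrame,
        truth: MinuteLabelSeries,
        feature_params: FeatureParams | None = None,
        theta_low_grid: np.ndarray | None = None,
        theta_noise_grid: np.ndarray | None = None,
    ) -> None:
        frame = (
            features
            if isinstance(features, pd.DataFrame)
            else features_to_frame(features)
        )
        self.feature_params = feature_params or FeatureParams()
        wpm = int(round(60.0 / self.feature_params.window_s))
        n_min = len(frame) // wpm
        if n_min < 1:
            raise DataError("need at least one full minute of feature windows")
        if truth.n_minutes < n_min:
            raise DataError("gold labels do not cover the feature windows")
        self._cum = frame["cum_activity"].to_numpy()[: n_min * wpm]
        self._hf = frame["hf_activity"].to_numpy()[: n_min * wpm]
        self._truth = truth.labels[:n_min].astype(np.int8)
        self._wpm = wpm
        if np.unique(self._truth).size < 2:
            raise CalibrationError("gold labels contain a single class")
        self.theta_low_grid = (
            np.asarray(theta_low_grid, dtype=float)
            if theta_low_grid is not None
            else self._default_grid(self._cum)
        )
        self.theta_noise_grid = (
            np.asarray(theta_noise_grid, dtype=float)
            if theta_noise_grid is not None
            else self._default_grid(self._hf)
        )

    @staticmethod
    def _default_grid(values: np.ndarray, n: int = 25) -> np.ndarray:
        qs = np.quantile(values, np.linspace(0.02, 0.98, n))
        qs = np.unique(qs[qs > 0])
        if qs.size == 0:
            qs = np.array([np.finfo(float).tiny])
        return qs

    def fit(self) -> "ThresholdBehaviourResults":
        best_score = -np.inf
        best = None
        for tl in self.theta_low_grid:
            for tn in self.theta_noise_grid:
                cfg = ClassifierConfig(
                    theta_low=float(tl),
                    theta_noise=float(tn),
                    features=self.feature_params,
                )
                labels, margins = _decide(self._cum, self._hf, cfg)
                pred = majority_vote(labels, margins, self._wpm)
                kappas = [
                    _one_vs_rest_kappa(self._truth, pred, int(c))
                    for c in TARGET_CLASSES
                ]
                score = float(np.nanmean(kappas))
                if score > best_score:
                    best_score = score
                    best = (cfg, kappas, pred)
        cfg, kappas, pred = best
        return ThresholdBehaviourResults(
            model=self,
            config=cfg,
            kappa_mean=best_score,
            kappa_by_class={
                c: k for c, k in zip(TARGET_CLASSES, kappas)
            },
            train_pred=pred,
            train_truth=self._truth,
        )


@dataclass
class ThresholdBehaviourResults:
    """Fitted thresholds with their training agreement."""

    model: ThresholdBehaviourModel
    config: ClassifierConfig
    kappa_mean: float
    kappa_by_class: dict[BehaviourLabel, float]
    train_pred: np.ndarray
    train_truth: np.ndarray

    def predict(self, trace: AccelTrace) -> MinuteLabelSeries:
        return classify_trace(trace, self.config)

    def summary(self) -> str:
        lines = [
            "Threshold behaviour classifier",
            "==============================",
            f"windows per minute      {int(round(60 / self.config.features.window_s))}"
            f"  (window {self.config.features.window_s:g} s)",
            f"theta_low  (g*s)        {self.config.theta_low:.4f}",
            f"theta_noise (g)         {self.config.theta_noise:.4f}",
            f"training minutes        {self.train_truth.size}",
            f"mean one-vs-rest kappa  {self.kappa_mean:.3f}",
        ]
        for c, k in self.kappa_by_class.items():
            lines.append(f"  kappa[{c.name.lower():<14s}] {k:.3f}")
        return "\n".join(lines)

    def plot_decision_plane(self, ax=None):
        """Scatter of training windows in the decision plane with the fitted
        thresholds; colours by gold minute label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        truth_per_window = np.repeat(self.train_truth, self.model._wpm)
        for c in TARGET_CLASSES:
            sel = truth_per_window == int(c)
            ax.scatter(
                self.model._cum[sel],
                self.model._hf[sel],
                s=4,
                alpha=0.4,
                label=c.name.lower(),
            )
        ax.axvline(self.config.theta_low, color="k", ls="--", lw=1)
        ax.axhline(self.config.theta_noise, color="k", ls=":", lw=1)
        ax.set_xlabel("cumulative activity (g·s)")
        ax.set_ylabel("high-frequency activity (g)")
        ax.legend()
        return ax


def calibrate(
    features: list[FeatureWindow] | pd.DataFrame,
    truth: MinuteLabelSeries,
    feature_params: FeatureParams | None = None,
    theta_low_grid: np.ndarray | None = None,
    theta_noise_grid: np.ndarray | None = None,
) -> ClassifierConfig:
    """Grid-search thresholds maximising mean one-vs-rest kappa (deterministic:
    first maximum in scan order wins).  See :class:`ThresholdBehaviourModel`."""
    model = ThresholdBehaviourModel(
        features,
        truth,
        feature_params=feature_params,
        theta_low_grid=theta_low_grid,
        theta_noise_grid=theta_noise_grid,
    )
    return model.fit().config
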