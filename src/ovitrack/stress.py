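"""Stress assessment from 24 h behaviour budgets.

A day of minute labels becomes a duration table (minutes per behaviour per
24 h, optionally split by posture).  Behaviour budgets of a baseline
condition (familiar group and pen) are compared with an unfamiliar condition
(pairwise separation and relocation) by a paired design: each condition's
sample is screened with the Shapiro–Wilk test and the paired two-sided
Student's t-test is used when both pass, otherwise the exact paired Wilcoxon
signed-rank test.  The variance-ratio F-test is reported as a diagnostic only
— variance equality does not bear on a paired design.

A simple deviation alert scores a new day against an animal's baseline days
in baseline-SD units (|z| ≥ k raises the alert), operationalising the use of
individual baselines for automated welfare monitoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ParameterError
from .io import BehaviourLabel, MinuteLabelSeries, Posture

__all__ = [
    "BASELINE",
    "UNFAMILIAR",
    "ComparisonResult",
    "DeviationAlert",
    "durations_from_labels",
    "validate_duration_table",
    "compare_conditions",
    "percent_change",
    "deviation_alert",
    "ConditionComparison",
    "ConditionComparisonResults",
    "read_duration_csv",
    "write_duration_csv",
]

BASELINE = "baseline"
UNFAMILIAR = "unfamiliar"
MINUTES_PER_DAY = 1440

_BEHAVIOUR_COL = {
    BehaviourLabel.RUMINATION: "rumination",
    BehaviourLabel.RESTING_IDLING: "resting_idling",
    BehaviourLabel.EATING: "eating",
    BehaviourLabel.OTHER: "other",
}
_BEHAVIOUR_FROM_COL = {v: k for k, v in _BEHAVIOUR_COL.items()}


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one paired baseline-vs-unfamiliar comparison."""

    behaviour: str
    posture: str
    n: int
    mean_baseline: float
    sd_baseline: float
    mean_unfamiliar: float
    sd_unfamiliar: float
    percent_change: float
    test_used: str  # "paired_t" | "paired_wilcoxon"
    p_value: float
    normality_p: float
    f_p: float  # variance-ratio diagnostic, not used for selection
    significant: bool
    degenerate: bool = False

    @property
    def stars(self) -> str:
        if self.degenerate or not np.isfinite(self.p_value):
            return ""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


@dataclass(frozen=True)
class DeviationAlert:
    """Baseline-deviation score for one animal/behaviour day."""

    score: float
    alert: bool
    degenerate: bool = False


def durations_from_labels(
    m: MinuteLabelSeries,
    condition: str,
    posture: np.ndarray | None = None,
    animal_id: str | None = None,
) -> pd.DataFrame:
    """Duration-table rows (minutes per behaviour per 24 h) from a full day.

    ``m`` must cover exactly 1440 minutes — partial days are rejected, since
    behaviour budgets are only comparable over whole days.  When a
    minute-level ``posture`` sequence (codes of :class:`~ovitrack.io.Posture`)
    is given, standing/lying splits are added; unknown-posture minutes count
    only towards the ``any`` rows.
    """
    if m.n_minutes != MINUTES_PER_DAY:
        raise DataError(
            f"need exactly {MINUTES_PER_DAY} minutes, got {m.n_minutes}"
        )
    animal = animal_id if animal_id is not None else m.animal_id
    rows = []
    for b, name in _BEHAVIOUR_COL.items():
        sel = m.labels == int(b)
        rows.append((animal, condition, name, "any", int(np.sum(sel))))
        if posture is not None:
            posture = np.asarray(posture, dtype=np.int8)
            if posture.size != MINUTES_PER_DAY:
                raise DataError("posture must cover 1440 minutes")
            for p, pname in (
                (Posture.STANDING, "standing"),
                (Posture.LYING, "lying"),
            ):
                rows.append(
                    (
                        animal,
                        condition,
                        name,
                        pname,
                        int(np.sum(sel & (posture == int(p)))),
                    )
                )
    return pd.DataFrame(
        rows, columns=["animal", "condition", "behaviour", "posture", "minutes"]
    )


def validate_duration_table(df: pd.DataFrame) -> None:
    """Check day-budget conservation: per (animal, condition) the ``any`` rows
    sum to 1440 minutes, and standing+lying equals ``any`` where a split is
    present."""
    for (animal, cond), grp in df.groupby(["animal", "condition"]):
        any_rows = grp[grp["posture"] == "any"]
        total = any_rows["minutes"].sum()
        if total != MINUTES_PER_DAY:
            raise DataError(
                f"animal {animal} / {cond}: behaviours sum to {total}, "
                f"expected {MINUTES_PER_DAY}"
            )
        for b, brows in grp.groupby("behaviour"):
            split = brows[brows["posture"].isin(["standing", "lying"])]
            if len(split) == 2:
                a = brows[brows["posture"] == "any"]["minutes"]
                if len(a) == 1 and split["minutes"].sum() != a.iloc[0]:
                    raise DataError(
                        f"animal {animal} / {cond} / {b}: "
                        "standing+lying does not equal the posture-free total"
                    )


def percent_change(mean_baseline: float, mean_unfamiliar: float) -> float:
    """Signed percent change relative to baseline; NaN if baseline is 0."""
    if mean_baseline == 0:
        return float("nan")
    return 100.0 * (mean_unfamiliar - mean_baseline) / mean_baseline


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro–Wilk p; a constant sample is maximally non-normal (p = 0)."""
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.shapiro(x).pvalue)


def _f_test_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided variance-ratio test p (R's var.test convention)."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 or vb == 0:
        return float("nan")
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2 * min(
        stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb)
    )
    return float(min(p, 1.0))


def compare_conditions(
    table: pd.DataFrame,
    behaviour: str | BehaviourLabel,
    posture: str = "any",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Paired comparison of one behaviour's daily duration across conditions.

    Test selection: Shapiro–Wilk on each condition's sample; if either
    rejects normality at ``alpha`` the exact paired Wilcoxon signed-rank test
    is used, otherwise the paired t-test.  Animals must match across
    conditions and there must be at least 3 pairs.
    """
    if isinstance(behaviour, BehaviourLabel):
        behaviour = _BEHAVIOUR_COL[behaviour]
    sel = (table["behaviour"] == behaviour) & (table["posture"] == posture)
    sub = table[sel]
    base = sub[sub["condition"] == BASELINE].set_index("animal")["minutes"]
    unf = sub[sub["condition"] == UNFAMILIAR].set_index("animal")["minutes"]
    if set(base.index) != set(unf.index):
        raise DataError("animal sets differ between conditions")
    if len(base) < 3:
        raise DataError("need at least 3 paired animals")
    animals = sorted(base.index)
    b = base.loc[animals].to_numpy(dtype=float)
    u = unf.loc[animals].to_numpy(dtype=float)
    diffs = u - b

    mean_b, sd_b = float(b.mean()), float(b.std(ddof=1))
    mean_u, sd_u = float(u.mean()), float(u.std(ddof=1))
    pct = percent_change(mean_b, mean_u)
    f_p = _f_test_p(b, u)

    if np.ptp(diffs) == 0 and diffs[0] == 0:
        # identical conditions: no paired test is informative
        return ComparisonResult(
            behaviour=behaviour,
            posture=posture,
            n=len(animals),
            mean_baseline=mean_b,
            sd_baseline=sd_b,
            mean_unfamiliar=mean_u,
            sd_unfamiliar=sd_u,
            percent_change=pct,
            test_used="paired_t",
            p_value=1.0,
            normality_p=float("nan"),
            f_p=f_p,
            significant=False,
            degenerate=True,
        )

    normality_p = min(_shapiro_p(b), _shapiro_p(u))
    if normality_p > alpha:
        test_used = "paired_t"
        p = float(stats.ttest_rel(u, b).pvalue)
    else:
        test_used = "paired_wilcoxon"
        try:
            p = float(
                stats.wilcoxon(
                    u, b, alternative="two-sided", method="exact"
                ).pvalue
            )
        except ValueError:
            # zeros/ties outside the exact distribution's support
            p = float(
                stats.wilcoxon(u, b, alternative="two-sided", method="auto").pvalue
            )
    return ComparisonResult(
        behaviour=behaviour,
        posture=posture,
        n=len(animals),
        mean_baseline=mean_b,
        sd_baseline=sd_b,
        mean_unfamiliar=mean_u,
        sd_unfamiliar=sd_u,
        percent_change=pct,
        test_used=test_used,
        p_value=p,
        normality_p=normality_p,
        f_p=f_p,
        significant=bool(p < alpha),
    )


def deviation_alert(
    baseline_minutes: np.ndarray,
    new_minutes: float,
    k: float = 2.0,
) -> DeviationAlert:
    """Score a new day's duration against the animal's baseline days.

    score = (new − baseline mean) / baseline SD; the alert fires when
    |score| ≥ k.  With a zero baseline SD the decision degrades to "any
    difference at all" and is flagged degenerate.
    """
    baseline_minutes = np.asarray(baseline_minutes, dtype=float)
    if baseline_minutes.size < 2:
        raise DataError("need at least 2 baseline days")
    mean = baseline_minutes.mean()
    sd = baseline_minutes.std(ddof=1)
    if sd == 0:
        diff = new_minutes - mean
        return DeviationAlert(
            score=float("inf") if diff != 0 else 0.0,
            alert=bool(diff != 0),
            degenerate=True,
        )
    score = (new_minutes - mean) / sd
    return DeviationAlert(score=float(score), alert=bool(abs(score) >= k))


class ConditionComparison:
    """Paired baseline-vs-unfamiliar analysis of a whole duration table.

    statsmodels-style: build from data, ``fit()`` runs every
    behaviour × posture comparison present in the table and returns a results
    object with a summary table.
    """

    def __init__(self, table: pd.DataFrame, alpha: float = 0.05) -> None:
        required = {"animal", "condition", "behaviour", "posture", "minutes"}
        missing = required - set(table.columns)
        if missing:
            raise DataError(f"duration table missing column(s) {sorted(missing)}")
        if not 0 < alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        self.table = table.copy()
        self.alpha = alpha

    @classmethod
    def from_csv(cls, path: str | Path, alpha: float = 0.05) -> "ConditionComparison":
        return cls(read_duration_csv(path), alpha=alpha)

    def fit(self) -> "ConditionComparisonResults":
        results = []
        combos = (
            self.table[["behaviour", "posture"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        for behaviour, posture in combos:
            results.append(
                compare_conditions(
                    self.table, behaviour, posture=posture, alpha=self.alpha
                )
            )
        return ConditionComparisonResults(model=self, results=results)


@dataclass
class ConditionComparisonResults:
    model: ConditionComparison
    results: list[ComparisonResult]

    def __getitem__(self, key: tuple[str, str] | str) -> ComparisonResult:
        behaviour, posture = key if isinstance(key, tuple) else (key, "any")
        for r in self.results:
            if r.behaviour == behaviour and r.posture == posture:
                return r
        raise KeyError(key)

    def summary(self) -> pd.DataFrame:
        """Table mirroring the published layout: mean±SD per condition,
        percent change, test († marks the exact signed-rank test), p and
        significance stars."""
        rows = []
        for r in self.results:
            rows.append(
                {
                    "behaviour": r.behaviour,
                    "posture": r.posture,
                    "n": r.n,
                    "mean_baseline": r.mean_baseline,
                    "sd_baseline": r.sd_baseline,
                    "mean_unfamiliar": r.mean_unfamiliar,
                    "sd_unfamiliar": r.sd_unfamiliar,
                    "percent_change": r.percent_change,
                    "test": "†" if r.test_used == "paired_wilcoxon" else "t",
                    "p_value": r.p_value,
                    "signif": r.stars,
                }
            )
        return pd.DataFrame(rows)


def read_duration_csv(path: str | Path) -> pd.DataFrame:
    """Read the ``animal,condition,behaviour,posture,minutes`` dialect."""
    df = pd.read_csv(path)
    required = {"animal", "condition", "behaviour", "minutes"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing column(s) {sorted(missing)}")
    if "posture" not in df.columns:
        df["posture"] = "any"
    df["animal"] = df["animal"].astype(str)
    return df


def write_duration_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
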