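"""Predictive performance evaluation for integer risk scores.

Discrimination is summarized by the AUC, computed as the rank statistic
AUC = P(score_case > score_control) + 0.5 * P(tie), which equals the
trapezoidal area under the empirical ROC curve.  Operating points use
the rule "positive iff score >= threshold" (consequential for integer
scores).  Confidence intervals are percentile bootstrap over episodes.
Calibration is reported as the observed event rate within score bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import CIError, DegenerateOutcomeError, UnattainableTargetError, ValidationError


def _check_labels(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise DegenerateOutcomeError("both outcome classes required")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_labels(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class ThresholdMetrics:
    """Operating-point metrics under the rule "positive iff score >= threshold".

    Ratios with a zero denominator (e.g. PPV when nothing is predicted
    positive) are reported as NaN, never as 0.  Bootstrap 95% CIs are
    attached when computed.
    """

    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    label: str = ""
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def confusion_metrics(scores, labels, threshold: float, label: str = "") -> ThresholdMetrics:
    """Sensitivity/specificity/PPV/NPV at one threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_labels(y)
    pos = s >= threshold
    tp = int(np.sum(pos & (y == 1)))
    fp = int(np.sum(pos & (y == 0)))
    fn = int(np.sum(~pos & (y == 1)))
    tn = int(np.sum(~pos & (y == 0)))

    def ratio(a: int, b: int) -> float:
        return a / b if b else float("nan")

    return ThresholdMetrics(
        threshold=float(threshold),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        label=label,
    )


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    return np.unique(scores)


def optimal_threshold(scores, labels) -> float:
    """Threshold nearest the upper-left corner of the ROC plane.

    Minimizes sqrt((1-sens)^2 + (1-spec)^2) over all achievable
    operating points; distance ties resolve to the lowest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_labels(y)
    best_t, best_d = None, np.inf
    for t in _candidate_thresholds(s):
        m = confusion_metrics(s, y, t)
        d = np.hypot(1 - m.sensitivity, 1 - m.specificity)
        if d < best_d - 1e-12:
            best_t, best_d = t, d
    return float(best_t)


def threshold_for_target(scores, labels, target: str, level: float) -> ThresholdMetrics:
    """Most conservative threshold reaching a sensitivity or specificity level.

    For sensitivity the LARGEST threshold with sens >= level (sensitivity
    falls as the threshold rises); for specificity the SMALLEST threshold
    with spec >= level.  Raises when no threshold attains the level.
    """
    if not 0 <= level <= 1:
        raise ValidationError("level must lie in [0, 1]")
    if target not in ("sensitivity", "specificity"):
        raise ValidationError("target must be 'sensitivity' or 'specificity'")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_labels(y)
    candidates = _candidate_thresholds(s)
    feasible = []
    for t in candidates:
        m = confusion_metrics(s, y, t, label=f"{target}~{level:.0%}")
        if getattr(m, target) >= level:
            feasible.append(m)
    if not feasible:
        raise UnattainableTargetError(f"no threshold reaches {target} >= {level}")
    if target == "sensitivity":
        return max(feasible, key=lambda m: m.threshold)
    return min(feasible, key=lambda m: m.threshold)


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    scores,
    labels,
    reps: int = 1000,
    seed: int = 0,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Percentile 95% CI of a metric over episode-resampled replicates.

    Rows are resampled with replacement; replicates missing an outcome
    class are redrawn.  NaN replicates are dropped, but if they exceed
    half of ``reps`` the interval is deemed undefined.
    """
    if reps < 100:
        raise ValidationError("at least 100 bootstrap replicates required")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_labels(y)
    rng = np.random.default_rng(seed)
    n = len(s)
    values = []
    for _ in range(reps):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
        else:
            raise CIError("could not draw a two-class bootstrap replicate")
        values.append(metric(s[idx], y[idx]))
    values = np.asarray(values, dtype=float)
    ok = values[~np.isnan(values)]
    if len(ok) < reps / 2:
        raise CIError("metric undefined on more than half of the bootstrap replicates")
    low, high = np.percentile(ok, [2.5, 97.5])
    return float(low), float(high)


def calibration_bins(scores, labels, edges: Sequence[float]) -> pd.DataFrame:
    """Observed event rate per score interval [e_i, e_{i+1}).

    ``edges`` are the full interval boundaries (at least two, strictly
    increasing); scores outside the outer edges are clipped into the
    first/last bin so the counts always conserve n.  Empty bins report a
    count of 0 and a NaN rate.
    """
    e = np.asarray(edges, dtype=float)
    if len(e) < 2 or np.any(np.diff(e) <= 0):
        raise ValidationError("edges must be >= 2 strictly increasing values")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    idx = np.clip(np.searchsorted(e, s, side="right") - 1, 0, len(e) - 2)
    rows = []
    for i in range(len(e) - 1):
        mask = idx == i
        count = int(mask.sum())
        rows.append(
            {
                "interval": f"[{e[i]:g}, {e[i + 1]:g})",
                "low": float(e[i]),
                "high": float(e[i + 1]),
                "n": count,
                "events": int(y[mask].sum()),
                "observed_rate": float(y[mask].mean()) if count else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def default_calibration_edges(scores, width: float = 10.0) -> np.ndarray:
    """Fixed-width score intervals spanning the observed range."""
    s = np.asarray(scores, dtype=float)
    lo = np.floor(s.min() / width) * width
    hi = np.floor(s.max() / width) * width + width
    return np.arange(lo, hi + width / 2, width)


@dataclass(frozen=True)
class EvalReport:
    """AUC with CI, operating-point rows and binned calibration."""

    auc: float
    auc_ci: tuple[float, float]
    thresholds: tuple[ThresholdMetrics, ...]
    calibration: pd.DataFrame
    n: int
    prevalence: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for m in self.thresholds:
            row = {
                "label": m.label,
                "threshold": m.threshold,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "ppv": m.ppv,
                "npv": m.npv,
            }
            for key, (lo, hi) in m.ci.items():
                row[f"{key}_ci_low"], row[f"{key}_ci_high"] = lo, hi
            rows.append(row)
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        def pct(x: float) -> str:
            return "NA" if np.isnan(x) else f"{100 * x:.1f}"

        lines = [
            "Classification rule: positive iff score >= threshold.",
            "",
            f"AUC {self.auc:.3f} (95% CI {self.auc_ci[0]:.3f}-{self.auc_ci[1]:.3f}), "
            f"n={self.n}, prevalence {100 * self.prevalence:.1f}%",
            "",
            "| Cutoff | Threshold | Sens (%) | Spec (%) | PPV (%) | NPV (%) |",
            "| --- | --- | --- | --- | --- | --- |",
        ]
        for m in self.thresholds:
            lines.append(
                f"| {m.label} | {m.threshold:g} | {pct(m.sensitivity)} | "
                f"{pct(m.specificity)} | {pct(m.ppv)} | {pct(m.npv)} |"
            )
        return "\n".join(lines)


def _with_cis(
    m: ThresholdMetrics, scores, labels, reps: int, seed: int
) -> ThresholdMetrics:
    ci = {}
    for i, name in enumerate(("sensitivity", "specificity", "ppv", "npv")):
        ci[name] = bootstrap_ci(
            lambda s, y, nm=name: getattr(confusion_metrics(s, y, m.threshold), nm),
            scores,
            labels,
            reps=reps,
            seed=seed + i,
        )
    return ThresholdMetrics(
        threshold=m.threshold,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        ppv=m.ppv,
        npv=m.npv,
        label=m.label,
        ci=ci,
    )


def evaluate_scores(
    scores,
    labels,
    reps: int = 1000,
    seed: int = 0,
    target_level: float = 0.95,
    calibration_edges: Sequence[float] | None = None,
) -> EvalReport:
    """Full evaluation: AUC + CI, three operating points, calibration bins.

    The three reported cutoffs are the upper-left-corner optimum and the
    thresholds at which sensitivity (resp. specificity) first reaches
    about ``target_level``; an unattainable target row is simply omitted.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    _check_labels(y)
    auc = roc_auc(s, y)
    auc_ci = bootstrap_ci(roc_auc, s, y, reps=reps, seed=seed)
    rows = []
    t_opt = optimal_threshold(s, y)
    rows.append(confusion_metrics(s, y, t_opt, label="optimal"))
    for target in ("sensitivity", "specificity"):
        try:
            rows.append(threshold_for_target(s, y, target, target_level))
        except UnattainableTargetError:
            pass
    rows = [_with_cis(m, s, y, reps, seed + 7 * i) for i, m in enumerate(rows)]
    edges = (
        np.asarray(calibration_edges, dtype=float)
        if calibration_edges is not None
        else default_calibration_edges(s)
    )
    calib = calibration_bins(s, y, edges)
    return EvalReport(
        auc=auc,
        auc_ci=auc_ci,
        thresholds=tuple(rows),
        calibration=calib,
        n=len(s),
        prevalence=float(y.mean()),
    )
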