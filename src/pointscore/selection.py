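"""Model-size selection via the parsimony curve, and cutoff fine-tuning.

For each candidate number of variables m, the top-m ranked variables are
binned on the training set, a score table is derived, and the INTEGER
score's AUC on the validation set is recorded — the deployed object is
the integer score, so the curve evaluates exactly that.  The user picks
m from the plot (manual mode, the intended human-in-the-loop usage) or
lets the plateau rule pick the smallest m whose gain to every larger
evaluated m is below delta.

Fine-tuning replaces automatically derived quantile cutoffs with
clinically conventional round values; the score must then be re-derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .cohort import CohortTable
from .errors import PointScoreError, SelectionError, ValidationError
from .evaluation import roc_auc
from .ranking import VariableRanking
from .score import (
    ScoreTable,
    derive_points,
    fit_weights,
    relevel_references,
    score_episodes,
)
from .transform import QuantileGrid, TransformSpec, apply_transform, derive_transform_spec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParsimonyCurve:
    """Validation AUC per candidate model size m."""

    points: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        ms = [m for m, _ in self.points]
        if ms != sorted(set(ms)):
            raise ValidationError("m values must be strictly increasing")

    @property
    def m_values(self) -> list[int]:
        return [m for m, _ in self.points]

    def auc(self, m: int) -> float:
        for mm, a in self.points:
            if mm == m:
                return a
        raise SelectionError(f"m={m} not on the curve")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["m", "auc"])


@dataclass(frozen=True)
class SelectionPolicy:
    """How to pick m: manual choice or automatic plateau detection."""

    mode: str = "auto"
    delta: float = 0.005
    m_max: int = 20
    manual_m: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "manual"):
            raise ValidationError("mode must be 'auto' or 'manual'")
        if self.delta <= 0:
            raise ValidationError("delta must be positive")
        if self.mode == "manual" and self.manual_m is None:
            raise ValidationError("manual mode requires manual_m")


def derive_score_for_variables(
    train: CohortTable,
    variables: list[str],
    grid: QuantileGrid,
    spec: TransformSpec | None = None,
) -> tuple[TransformSpec, ScoreTable]:
    """Bin the given variables on train, fit + relevel weights, derive points."""
    if spec is None:
        spec = derive_transform_spec(train, variables, grid)
    train_cat = apply_transform(train, spec)
    fit = fit_weights(train_cat, spec.variables, train.outcome)
    fit = relevel_references(fit, train_cat, train.outcome)
    return spec, derive_points(fit)


def parsimony_curve(
    train: CohortTable,
    validation: CohortTable,
    ranking: VariableRanking,
    grid: QuantileGrid = QuantileGrid(),
    m_values: list[int] | None = None,
) -> ParsimonyCurve:
    """Validation AUC of the integer score for each candidate m.

    Any m whose derivation fails (e.g. a degenerate variable) is recorded
    as a gap rather than aborting the whole curve.  Deterministic given
    the upstream seeds.
    """
    if m_values is None:
        m_values = list(range(1, min(20, len(ranking)) + 1))
    if any(m < 1 or m > len(ranking) for m in m_values):
        raise ValidationError("m values must lie in 1..number of ranked variables")
    points = []
    for m in sorted(set(m_values)):
        try:
            spec = derive_transform_spec(train, ranking.top(m), grid)
            _, table = derive_score_for_variables(train, ranking.top(m), grid, spec=spec)
            scores = score_episodes(apply_transform(validation, spec), table)
            points.append((m, roc_auc(scores, validation.y)))
        except PointScoreError as exc:  # leave a gap, keep the curve
            logger.warning("parsimony curve: m=%d failed (%s)", m, exc)
    return ParsimonyCurve(points=tuple(points))


def select_m(curve: ParsimonyCurve, policy: SelectionPolicy = SelectionPolicy()) -> int:
    """Pick the model size from the parsimony curve.

    Auto mode returns the smallest m such that no larger evaluated m
    improves the AUC by ``delta`` or more; manual mode validates and
    returns the user's choice.
    """
    if not curve.points:
        raise SelectionError("empty parsimony curve")
    if policy.mode == "manual":
        if policy.manual_m not in curve.m_values:
            raise SelectionError(f"manual m={policy.manual_m} not on the curve")
        return int(policy.manual_m)
    for m, auc_m in curve.points:
        if all(a - auc_m < policy.delta for mm, a in curve.points if mm > m):
            return int(m)
    return int(curve.points[-1][0])


def fine_tune_cutoffs(
    spec: TransformSpec, overrides: dict[str, list[float]]
) -> TransformSpec:
    """Replace automatic cutoffs with hand-chosen ones (round clinical values).

    Each override must be strictly increasing and refer to a continuous
    variable already in the spec.  The caller re-runs transformation and
    score derivation afterwards.
    """
    cutoffs = dict(spec.cutoffs)
    for name, cuts in overrides.items():
        if name not in cutoffs:
            raise ValidationError(f"override for unknown continuous variable {name!r}")
        arr = [float(c) for c in cuts]
        if arr != sorted(set(arr)) or not arr:
            raise ValidationError(f"override cutoffs for {name!r} must be strictly increasing")
        cutoffs[name] = tuple(arr)
    return replace(spec, cutoffs=cutoffs)
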