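"""Score derivation: category-level logistic weights to integer points.

The model is a multivariable logistic regression on the categorized
predictors,

    logit P(Y=1) = beta_0 + sum_v sum_c beta_{v,c} * 1[X_v = c]

with one reference category per variable (coefficient 0).  Derivation is
a three-step pipeline:

1. fit the weights (a small ridge penalty, lambda = 1e-4 on the slopes
   only, keeps estimates finite under quasi-separation);
2. relevel: the category with the lowest first-pass coefficient becomes
   the reference and the model is refitted, so all remaining
   coefficients are nonnegative (rare residual negatives are clamped to
   zero and logged);
3. convert to points: divide every coefficient by the smallest positive
   coefficient across all variables (beta_lowest) and round half away
   from zero, so the least influential category maps to one point.

The total score of an episode is the sum of its per-variable points.
An optional ceiling rescales all points by ceiling/max_total for scores
that must fit a conventional range.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .errors import (
    DegenerateOutcomeError,
    NoSignalError,
    ScoringError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: ridge penalty on slope coefficients (objective: sum loss + RIDGE/2 * ||b||^2)
RIDGE_LAMBDA = 1e-4
#: coefficients at or below this are treated as numerically zero
EPS_COEF = 1e-6
#: |beta| beyond this flags quasi-separation
SEPARATION_BOUND = 10.0


def round_half_away_from_zero(x: float) -> int:
    """Round with .5 going away from zero (2.5 -> 3), the convention of
    clinical scoring tables; Python's builtin round is banker's rounding."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class WeightFit:
    """A fitted category-level logistic model.

    ``coefs`` holds, per variable, the coefficient of every non-reference
    category (reference implicitly 0).  ``raw_coefs`` preserves the
    un-clamped maximum-likelihood values; ``coefs`` may have had residual
    negatives clamped to zero after releveling.
    """

    intercept: float
    coefs: dict[str, dict[str, float]]
    raw_coefs: dict[str, dict[str, float]]
    references: dict[str, str]
    categories: dict[str, list[str]]
    converged: bool = True
    separation: bool = False

    @property
    def variables(self) -> list[str]:
        return list(self.categories)

    def coefficient(self, variable: str, category: str, raw: bool = False) -> float:
        """Coefficient of a category, 0.0 for the reference."""
        if category == self.references[variable]:
            return 0.0
        table = self.raw_coefs if raw else self.coefs
        return table[variable][category]


def _design(
    cat_table: pd.DataFrame,
    variables: list[str],
    references: dict[str, str],
    categories: dict[str, list[str]],
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    cols, names = [], []
    for var in variables:
        col = cat_table[var].astype(str).to_numpy()
        for cat in categories[var]:
            if cat == references[var]:
                continue
            cols.append((col == cat).astype(float))
            names.append((var, cat))
    return np.column_stack(cols), names


def fit_weights(
    cat_table: pd.DataFrame,
    variables: list[str],
    outcome: str,
    references: dict[str, str] | None = None,
) -> WeightFit:
    """Maximum-likelihood logistic fit on one-hot category indicators.

    ``references`` picks the omitted category per variable (default: the
    first category in category order).  The ridge term guarantees finite
    estimates when a category has zero events; such fits are flagged via
    ``separation`` when any |beta| exceeds 10.
    """
    y = cat_table[outcome].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("both outcome classes required to fit weights")
    categories: dict[str, list[str]] = {}
    for var in variables:
        col = cat_table[var]
        if isinstance(col.dtype, pd.CategoricalDtype):
            cats = [c for c in col.cat.categories if (col == c).any()]
        else:
            cats = sorted(col.astype(str).unique())
        if len(cats) < 2:
            raise ValidationError(f"variable {var!r} has a single observed category")
        categories[var] = cats
    if references is None:
        references = {var: categories[var][0] for var in variables}
    X, names = _design(cat_table, variables, references, categories)
    # L2 penalty (sklearn default) with C = 1/lambda; intercept unpenalized
    clf = LogisticRegression(
        C=1.0 / RIDGE_LAMBDA,
        solver="lbfgs",
        max_iter=1000,
        tol=1e-8,
    )
    clf.fit(X, y)
    beta = clf.coef_[0]
    coefs: dict[str, dict[str, float]] = {var: {} for var in variables}
    for (var, cat), b in zip(names, beta):
        coefs[var][cat] = float(b)
    return WeightFit(
        intercept=float(clf.intercept_[0]),
        coefs={v: dict(d) for v, d in coefs.items()},
        raw_coefs={v: dict(d) for v, d in coefs.items()},
        references=dict(references),
        categories=categories,
        converged=bool(clf.n_iter_[0] < clf.max_iter),
        separation=bool(np.any(np.abs(beta) > SEPARATION_BOUND)),
    )


def relevel_references(
    fit: WeightFit, cat_table: pd.DataFrame, outcome: str
) -> WeightFit:
    """Re-reference each variable at its lowest-risk category and refit.

    The first-pass coefficients (old reference = 0) identify, per
    variable, the category with the lowest fitted log-odds; a second
    logistic regression with those references makes every remaining
    coefficient nonnegative up to sampling noise.  Residual negatives are
    clamped to zero (the raw values stay available on ``raw_coefs``).
    """
    new_refs: dict[str, str] = {}
    for var in fit.variables:
        cats = fit.categories[var]
        new_refs[var] = min(cats, key=lambda c: (fit.coefficient(var, c), cats.index(c)))
    refit = fit_weights(cat_table, fit.variables, outcome, references=new_refs)
    clamped = {v: dict(d) for v, d in refit.coefs.items()}
    n_clamped = 0
    for var, d in clamped.items():
        for cat, b in d.items():
            if b < 0:
                d[cat] = 0.0
                n_clamped += 1
    if n_clamped:
        logger.warning(
            "clamped %d residual negative coefficient(s) to zero after releveling",
            n_clamped,
        )
    return replace(refit, coefs=clamped)


@dataclass(frozen=True)
class ScoreTable:
    """Integer points per category of each variable — the deployable score.

    ``points[var][category]`` is a nonnegative integer; each variable's
    reference category scores 0.  ``min_total``/``max_total`` bound the
    total of any episode.  When a ceiling normalization was applied,
    ``ceiling`` and the common ``denominator`` it divided by are recorded.
    """

    points: dict[str, dict[str, int]]
    references: dict[str, str]
    ceiling: int | None = None
    denominator: float | None = None
    category_order: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, d in self.points.items():
            for cat, p in d.items():
                if p < 0 or p != int(p):
                    raise ValidationError(f"point {var}/{cat} must be a nonnegative integer")
            ref = self.references.get(var)
            if ref is None or d.get(ref, 0) != 0:
                raise ValidationError(f"reference category of {var!r} must score 0")

    @property
    def variables(self) -> list[str]:
        return list(self.points)

    @property
    def min_total(self) -> int:
        return int(sum(min(d.values()) for d in self.points.values()))

    @property
    def max_total(self) -> int:
        return int(sum(max(d.values()) for d in self.points.values()))

    def to_json(self) -> str:
        obj = {
            "points": self.points,
            "references": self.references,
            "min_total": self.min_total,
            "max_total": self.max_total,
            "ceiling": self.ceiling,
            "denominator": self.denominator,
            "category_order": self.category_order or None,
        }
        return json.dumps(obj, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScoreTable":
        obj = json.loads(text)
        return cls(
            points={v: {c: int(p) for c, p in d.items()} for v, d in obj["points"].items()},
            references=dict(obj["references"]),
            ceiling=obj.get("ceiling"),
            denominator=obj.get("denominator"),
            category_order=obj.get("category_order") or {},
        )

    def _ordered_cats(self, var: str) -> list[str]:
        return self.category_order.get(var) or sorted(self.points[var])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"variable": var, "interval": cat, "point": self.points[var][cat]}
            for var in self.variables
            for cat in self._ordered_cats(var)
        ]
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = ["| Variable and interval | Point |", "| --- | --- |"]
        for var in self.variables:
            lines.append(f"| **{var}** | |")
            for cat in self._ordered_cats(var):
                lines.append(f"| {cat} | {self.points[var][cat]} |")
        return "\n".join(lines)


def derive_points(fit: WeightFit) -> ScoreTable:
    """Convert releveled coefficients to integer points via beta_lowest.

    beta_lowest is the smallest coefficient strictly greater than 1e-6
    across all variables; every coefficient is divided by it and rounded
    half away from zero.  Reference categories score 0.
    """
    positives = [
        b for d in fit.coefs.values() for b in d.values() if b > EPS_COEF
    ]
    if not positives:
        raise NoSignalError("no coefficient exceeds the zero threshold; score is empty")
    beta_lowest = min(positives)
    points: dict[str, dict[str, int]] = {}
    for var in fit.variables:
        points[var] = {}
        for cat in fit.categories[var]:
            b = fit.coefficient(var, cat)
            points[var][cat] = round_half_away_from_zero(max(b, 0.0) / beta_lowest)
        points[var][fit.references[var]] = 0
    return ScoreTable(
        points=points,
        references=dict(fit.references),
        category_order={v: list(c) for v, c in fit.categories.items()},
    )


def normalize_to_ceiling(table: ScoreTable, ceiling: int) -> ScoreTable:
    """Rescale points so the maximum total is about ``ceiling``.

    Each point is multiplied by ceiling/max_total and rounded half away
    from zero, so the post-rounding maximum can exceed the ceiling by at
    most one point per variable.  References stay at 0.
    """
    if ceiling < len(table.variables):
        raise ValidationError(
            "ceiling below the number of variables would collapse the score"
        )
    if table.max_total <= 0:
        raise ValidationError("max_total must be positive to normalize")
    factor = ceiling / table.max_total
    points = {
        var: {cat: round_half_away_from_zero(p * factor) for cat, p in d.items()}
        for var, d in table.points.items()
    }
    return replace(
        table,
        points=points,
        ceiling=int(ceiling),
        denominator=table.max_total / ceiling,
    )


def compute_score(episode: Mapping[str, str], table: ScoreTable) -> int:
    """Total integer score of one categorized episode.

    Unknown categories fall back to "Other" when the variable has one,
    else to the 0-point reference; a missing variable is an error.
    """
    total = 0
    for var in table.variables:
        if var not in episode:
            raise ScoringError(f"episode lacks a category for variable {var!r}")
        cat = str(episode[var])
        d = table.points[var]
        if cat in d:
            total += d[cat]
        elif "Other" in d:
            total += d["Other"]
        else:
            total += d[table.references[var]]
    return int(total)


def score_episodes(cat_table: pd.DataFrame, table: ScoreTable) -> np.ndarray:
    """Vectorized :func:`compute_score` over a categorized table."""
    total = np.zeros(len(cat_table), dtype=int)
    for var in table.variables:
        if var not in cat_table.columns:
            raise ScoringError(f"table lacks a category column for {var!r}")
        d = table.points[var]
        fallback = d.get("Other", 0)
        mapped = cat_table[var].astype(str).map(lambda c: d.get(c, fallback))
        total += mapped.to_numpy(dtype=int)
    return total


def linear_predictor(cat_table: pd.DataFrame, fit: WeightFit) -> np.ndarray:
    """Per-row fitted log-odds beta_0 + sum of category coefficients (raw)."""
    lp = np.full(len(cat_table), fit.intercept, dtype=float)
    for var in fit.variables:
        col = cat_table[var].astype(str).to_numpy()
        for cat in fit.categories[var]:
            b = fit.coefficient(var, cat, raw=True)
            if b != 0.0:
                lp += b * (col == cat)
    return lp


def prerounding_scores(cat_table: pd.DataFrame, fit: WeightFit) -> np.ndarray:
    """Per-row continuous score sum(beta_raw)/beta_lowest before rounding.

    Uses the un-clamped coefficients, so this is an exact affine transform
    of :func:`linear_predictor` — their AUCs agree to machine precision.
    """
    positives = [b for d in fit.coefs.values() for b in d.values() if b > EPS_COEF]
    if not positives:
        raise NoSignalError("no positive coefficient")
    beta_lowest = min(positives)
    return (linear_predictor(cat_table, fit) - fit.intercept) / beta_lowest
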