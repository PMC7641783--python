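"""Variable ranking by random-forest mean decrease in Gini impurity.

A random forest of classification trees is grown on the training
partition (bootstrap sample per tree, sqrt(p) candidate variables per
split, trees grown to maximum size without pruning).  The importance of
a variable is the raw mean decrease impurity

    Imp(X) = (1/N_T) * sum_trees sum_{nodes tau splitting on X} w(tau) * dGini(tau)

where ``w(tau) = N_tau / N`` is the fraction of samples reaching the node
and ``dGini(tau)`` the impurity reduction of its split.  Only the ORDER of
importances is consumed downstream, so no normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cohort import CATEGORICAL, CohortTable
from .errors import DegenerateOutcomeError, ValidationError


@dataclass(frozen=True)
class RFConfig:
    """Forest hyper-parameters: 100 trees, sqrt(p) variables per split."""

    n_trees: int = 100
    mtry_rule: str = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.mtry_rule != "sqrt":
            raise ValidationError("only the sqrt mtry rule is supported")


@dataclass(frozen=True)
class VariableRanking:
    """Variables ordered by importance, descending; ties broken by name."""

    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        imps = [imp for _, imp in self.entries]
        if any(i < 0 for i in imps):
            raise ValidationError("importances must be nonnegative")
        if list(imps) != sorted(imps, reverse=True):
            raise ValidationError("ranking must be sorted by importance, descending")
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate variable in ranking")

    @property
    def variables(self) -> list[str]:
        return [name for name, _ in self.entries]

    def top(self, m: int) -> list[str]:
        return self.variables[:m]

    def __len__(self) -> int:
        return len(self.entries)

    def to_records(self) -> list[dict]:
        return [{"variable": n, "importance": float(i)} for n, i in self.entries]


def gini_index(class_fractions) -> float:
    """Gini impurity ``1 - sum_r p_r**2`` of a node's class fractions.

    For binary classification (R = 2) the value lies in [0, 0.5].
    """
    p = np.asarray(class_fractions, dtype=float)
    if (p < 0).any():
        raise ValidationError("class fractions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValidationError("class fractions must sum to 1")
    return float(1.0 - np.square(p).sum())


def encode_by_outcome_rate(
    col: pd.Series, y: np.ndarray
) -> tuple[np.ndarray, dict[str, int]]:
    """Integer-code a categorical column by ascending outcome rate.

    Ordering levels by their event rate makes the single-threshold split
    search of a binary tree as expressive on the categorical variable as
    an optimal subset split, while keeping the design matrix one column.
    Ties in rate are broken by level name for determinism.
    """
    rates = (
        pd.DataFrame({"level": col.astype(str), "y": y})
        .groupby("level", sort=True)["y"]
        .mean()
    )
    ordered = sorted(rates.index, key=lambda lv: (rates[lv], lv))
    codes = {lv: i for i, lv in enumerate(ordered)}
    return col.astype(str).map(codes).to_numpy(dtype=float), codes


def _design_matrix(train: CohortTable) -> tuple[np.ndarray, list[str]]:
    y = train.y
    cols = []
    names = []
    for name in train.predictors:
        if train.var_kinds[name] == CATEGORICAL:
            encoded, _ = encode_by_outcome_rate(train.data[name], y)
            cols.append(encoded)
        else:
            cols.append(train.data[name].to_numpy(dtype=float))
        names.append(name)
    return np.column_stack(cols), names


def raw_mean_decrease_impurity(forest: RandomForestClassifier) -> np.ndarray:
    """Average the UNnormalized per-tree impurity decreases over the forest."""
    total = np.zeros(forest.n_features_in_)
    for est in forest.estimators_:
        total += est.tree_.compute_feature_importances(normalize=False)
    return total / len(forest.estimators_)


def rank_variables(train: CohortTable, config: RFConfig = RFConfig()) -> VariableRanking:
    """Rank all candidate predictors by mean decrease in Gini impurity.

    Reproducible for a fixed ``config.seed``; importance ties are broken
    by variable name (ascending) so the ranking is fully deterministic.
    """
    if train.n < 2:
        raise ValidationError("need at least 2 training rows to rank variables")
    y = train.y
    if len(np.unique(y)) < 2:
        raise DegenerateOutcomeError("both outcome classes required for ranking")
    X, names = _design_matrix(train)
    if np.isnan(X).any():
        raise ValidationError("missing values present; impute before ranking")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    importances = raw_mean_decrease_impurity(forest)
    order = sorted(range(len(names)), key=lambda i: (-importances[i], names[i]))
    entries = tuple((names[i], float(importances[i])) for i in order)
    return VariableRanking(entries=entries)
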