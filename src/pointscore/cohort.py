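"""Cohort loading, cleaning and partitioning.

A cohort is a rectangular table of care episodes: one row per episode,
columns holding candidate predictors (continuous vitals/labs plus
categorical demographics) and a binary outcome (1 = event, e.g. inpatient
mortality).  This module covers the data-hygiene steps that precede any
modelling: physical-plausibility outlier screening (out-of-range values
become missing), a random train/validation/test split, and imputation of
the remaining missing values using statistics computed on the training
partition only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ImputationError,
    SchemaError,
    SizeError,
    ValidationError,
)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: label assigned to missing categorical cells at imputation time
UNKNOWN_LEVEL = "Unknown"

_NA_STRINGS = {"", "na", "n/a", "nan", "null", "none", "missing", "."}


@dataclass(frozen=True)
class CohortTable:
    """Episodes-by-variables table with a binary outcome column.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per episode.  Continuous predictors are float columns
        (``NaN`` = missing); categorical predictors are object/string
        columns (``NaN``/``None`` = missing).
    outcome : str
        Name of the binary outcome column; values must be 0/1 with no
        missing entries.
    var_kinds : dict
        ``variable name -> "continuous" | "categorical"`` for every
        predictor column.
    """

    data: pd.DataFrame
    outcome: str
    var_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in self.data.columns:
            raise SchemaError(f"outcome column {self.outcome!r} not in table")
        y = self.data[self.outcome]
        if y.isna().any():
            raise ValidationError("outcome column contains missing values")
        bad = set(pd.unique(y)) - {0, 1}
        if bad:
            raise ValidationError(f"outcome values must be 0/1, found {sorted(bad)!r}")
        if len(self.data) < 1:
            raise ValidationError("cohort must contain at least one row")
        for name, kind in self.var_kinds.items():
            if name not in self.data.columns:
                raise SchemaError(f"declared variable {name!r} missing from table")
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise ValidationError(f"unknown variable kind {kind!r} for {name!r}")
        undeclared = [
            c for c in self.data.columns if c != self.outcome and c not in self.var_kinds
        ]
        if undeclared:
            raise SchemaError(f"predictor columns without declared kind: {undeclared}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.data.columns if c != self.outcome]

    @property
    def y(self) -> np.ndarray:
        return self.data[self.outcome].to_numpy(dtype=int)

    def continuous_variables(self) -> list[str]:
        return [v for v in self.predictors if self.var_kinds[v] == CONTINUOUS]

    def categorical_variables(self) -> list[str]:
        return [v for v in self.predictors if self.var_kinds[v] == CATEGORICAL]

    def with_data(self, data: pd.DataFrame) -> "CohortTable":
        return replace(self, data=data)


@dataclass(frozen=True)
class PlausibilityRanges:
    """Per-variable physical plausibility bounds, in the variable's units.

    Values outside ``[low, high]`` are treated as recording artefacts
    (e.g. a heart rate of 400 beats/min) and set to missing.
    """

    ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (low, high) in self.ranges.items():
            if not low < high:
                raise ValidationError(f"range for {name!r}: low must be < high")


@dataclass(frozen=True)
class SplitSpec:
    """Proportions and seed for the random train/validation/test split."""

    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0
    stratify: bool = False

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValidationError("three positive split fractions required")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")


def _clean_cell(value) -> object:
    if isinstance(value, str) and value.strip().lower() in _NA_STRINGS:
        return np.nan
    return value


def load_cohort(
    path,
    schema: dict[str, str],
    outcome_name: str,
) -> CohortTable:
    """Read a CSV/TSV cohort file into a typed :class:`CohortTable`.

    ``schema`` maps each predictor column to ``"continuous"`` or
    ``"categorical"``.  Missing cells may be empty or any of the common
    NA spellings ("NA", "n/a", ...).  Unparseable cells in continuous
    columns become missing rather than raising.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if outcome_name not in raw.columns:
        raise SchemaError(f"outcome column {outcome_name!r} not found in {path}")

    df = pd.DataFrame(index=raw.index)
    y = pd.to_numeric(raw[outcome_name].map(_clean_cell), errors="coerce")
    if y.isna().any():
        raise ValidationError("outcome column contains missing/unparseable values")
    if not set(pd.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("outcome column must contain only 0 and 1")
    df[outcome_name] = y.astype(int)

    for name, kind in schema.items():
        if name not in raw.columns:
            raise SchemaError(f"declared variable {name!r} not found in {path}")
        col = raw[name].map(_clean_cell)
        if kind == CONTINUOUS:
            df[name] = pd.to_numeric(col, errors="coerce").astype(float)
        elif kind == CATEGORICAL:
            df[name] = col.astype(object).where(col.notna(), np.nan)
        else:
            raise ValidationError(f"unknown kind {kind!r} for variable {name!r}")

    return CohortTable(data=df, outcome=outcome_name, var_kinds=dict(schema))


def flag_outliers(cohort: CohortTable, ranges: PlausibilityRanges) -> CohortTable:
    """Set values outside their plausibility range to missing.

    Only continuous variables may carry ranges; everything else is
    returned unchanged.  A new table is returned.
    """
    df = cohort.data.copy()
    for name, (low, high) in ranges.ranges.items():
        if name not in cohort.var_kinds:
            raise ConfigurationError(f"plausibility range for unknown variable {name!r}")
        if cohort.var_kinds[name] != CONTINUOUS:
            raise ConfigurationError(
                f"plausibility range given for categorical variable {name!r}"
            )
        col = df[name]
        df[name] = col.where(col.isna() | ((col >= low) & (col <= high)), np.nan)
    return cohort.with_data(df)


def _split_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    n_train = int(round(n * fractions[0]))
    n_val = int(round(n * fractions[1]))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise SizeError(f"split of n={n} with fractions {fractions} leaves an empty partition")
    return n_train, n_val, n_test


def split_cohort(
    cohort: CohortTable, spec: SplitSpec
) -> tuple[CohortTable, CohortTable, CohortTable]:
    """Randomly partition the cohort into train/validation/test tables.

    The split is a simple random permutation by default; with
    ``spec.stratify`` the permutation is applied within each outcome
    class so small cohorts keep both classes in every partition.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    idx = np.arange(cohort.n)
    if spec.stratify:
        y = cohort.y
        parts: list[list[np.ndarray]] = [[], [], []]
        for cls in (0, 1):
            cls_idx = rng.permutation(idx[y == cls])
            a, b, _ = _split_sizes(len(cls_idx), spec.fractions)
            parts[0].append(cls_idx[:a])
            parts[1].append(cls_idx[a : a + b])
            parts[2].append(cls_idx[a + b :])
        assign = [np.concatenate(p) for p in parts]
        if min(len(a) for a in assign) < 1:
            raise SizeError("stratified split leaves an empty partition")
    else:
        perm = rng.permutation(idx)
        a, b, _ = _split_sizes(cohort.n, spec.fractions)
        assign = [perm[:a], perm[a : a + b], perm[a + b :]]
    out = []
    for rows in assign:
        out.append(cohort.with_data(cohort.data.iloc[np.sort(rows)].copy()))
    return tuple(out)


def impute_from_training(
    train: CohortTable, others: list[CohortTable]
) -> tuple[CohortTable, list[CohortTable]]:
    """Fill missing cells everywhere using training-set statistics only.

    Continuous missing cells (in train and every other partition) are
    replaced by the training median of the observed values; categorical
    missing cells become the explicit ``"Unknown"`` level, treating
    missingness as its own (potentially informative) category.
    """
    medians: dict[str, float] = {}
    for name in train.continuous_variables():
        observed = train.data[name].dropna()
        if observed.empty:
            raise ImputationError(f"variable {name!r} has no observed training values")
        medians[name] = float(observed.median())

    def fill(tbl: CohortTable) -> CohortTable:
        df = tbl.data.copy()
        for name, med in medians.items():
            df[name] = df[name].fillna(med)
        for name in tbl.categorical_variables():
            col = df[name]
            df[name] = col.where(col.notna(), UNKNOWN_LEVEL)
        return tbl.with_data(df)

    return fill(train), [fill(t) for t in others]
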