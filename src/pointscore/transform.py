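"""Variable transformation: quantile binning and category capping.

Continuous predictors are stratified into at most K ordered categories
using the training-set percentiles at k1, k2, k3, k4 (defaults 5, 20,
80, 95 — tails of 5% and 15% around a 60% central band, appropriate for
near-normally distributed vitals and labs).  Bins follow the left-closed
convention: a value equal to a cutoff belongs to the bin ABOVE it, so the
bins are (-inf, c1), [c1, c2), ..., [c_j, +inf) with labels "<c1",
"c1-c2", ..., ">=c_j".

Categorical predictors with more than K observed levels have their rarest
levels pooled into an "Other" category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CATEGORICAL, CONTINUOUS, CohortTable
from .errors import ConfigurationError, DegenerateVariableError, ValidationError

OTHER_LEVEL = "Other"


@dataclass(frozen=True)
class QuantileGrid:
    """Percentile grid (k1..k4) and maximum category count K."""

    k1: float = 5.0
    k2: float = 20.0
    k3: float = 80.0
    k4: float = 95.0
    max_categories: int = 5

    def __post_init__(self) -> None:
        ks = (self.k1, self.k2, self.k3, self.k4)
        if not all(0 < a < 100 for a in ks) or not all(
            a < b for a, b in zip(ks, ks[1:])
        ):
            raise ValidationError("quantile grid must satisfy 0 < k1 < k2 < k3 < k4 < 100")
        if self.max_categories < 2:
            raise ValidationError("max_categories must be >= 2")

    @property
    def percentiles(self) -> tuple[float, float, float, float]:
        return (self.k1, self.k2, self.k3, self.k4)


def _fmt(x: float) -> str:
    """Compact numeric label: integers bare, else shortest round-trip float."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def bin_labels(cutoffs) -> list[str]:
    """Printable labels for the bins implied by a cutoff vector."""
    c = [_fmt(v) for v in cutoffs]
    labels = [f"<{c[0]}"]
    labels += [f"{a}-{b}" for a, b in zip(c[:-1], c[1:])]
    labels.append(f">={c[-1]}")
    return labels


def derive_cutoffs(values, grid: QuantileGrid = QuantileGrid()) -> tuple[float, ...]:
    """Percentile cutoffs at k1..k4 (linear interpolation), deduplicated.

    Heavily tied variables can yield duplicate percentiles; these collapse
    so the returned vector has between 1 and 4 strictly increasing entries.
    A constant variable cannot be binned and raises
    :class:`DegenerateVariableError`.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if np.unique(v).size < 2:
        raise DegenerateVariableError("fewer than 2 distinct observed values")
    cuts = np.percentile(v, grid.percentiles, method="linear")
    cuts = np.unique(cuts)
    if cuts.size < 1:
        raise DegenerateVariableError("no usable cutoffs")
    return tuple(float(c) for c in cuts)


def bin_index(value: float, cutoffs) -> int:
    """0-based bin of ``value``: count of cutoffs <= value (left-closed bins)."""
    return int(np.searchsorted(np.asarray(cutoffs, dtype=float), value, side="right"))


def categorize_continuous(value: float, cutoffs) -> str:
    """Label of the bin containing ``value`` (a total function on the reals)."""
    return bin_labels(cutoffs)[bin_index(value, cutoffs)]


def merge_categories(level_counts: dict[str, int], max_categories: int) -> dict[str, str]:
    """Map raw levels to at most ``max_categories`` output levels.

    If the level count already fits, the identity map is returned.
    Otherwise the most frequent K-1 levels are kept and the rest pooled
    into "Other"; frequency ties are broken by level name so the result
    is deterministic.
    """
    if max_categories < 2:
        raise ValidationError("max_categories must be >= 2")
    if not level_counts:
        raise ValidationError("empty level set")
    levels = sorted(level_counts, key=lambda lv: (-level_counts[lv], lv))
    if len(levels) <= max_categories:
        return {lv: lv for lv in levels}
    keep = set(levels[: max_categories - 1])
    return {lv: (lv if lv in keep else OTHER_LEVEL) for lv in levels}


@dataclass(frozen=True)
class TransformSpec:
    """Per-variable categorization rules, the editable fine-tuning surface.

    ``cutoffs`` holds the ordered cutoff vector per continuous variable;
    ``level_maps`` the raw-level -> merged-level map per categorical one.
    Serialized to JSON so cutoffs can be hand-edited (rounded, combined)
    and the score re-derived.
    """

    cutoffs: dict[str, tuple[float, ...]] = field(default_factory=dict)
    level_maps: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, cuts in self.cutoffs.items():
            arr = list(cuts)
            if arr != sorted(set(arr)):
                raise ValidationError(f"cutoffs for {name!r} must be strictly increasing")
            if not arr:
                raise ValidationError(f"empty cutoff vector for {name!r}")

    @property
    def variables(self) -> list[str]:
        return list(self.cutoffs) + list(self.level_maps)

    def categories(self, name: str) -> list[str]:
        """Ordered output categories of a variable under this spec."""
        if name in self.cutoffs:
            return bin_labels(self.cutoffs[name])
        levels = self.level_maps[name]
        seen: list[str] = []
        for lv in sorted(levels, key=lambda raw: (levels[raw] == OTHER_LEVEL, raw)):
            out = levels[lv]
            if out not in seen:
                seen.append(out)
        return seen

    def to_json(self) -> str:
        obj = {}
        for name, cuts in self.cutoffs.items():
            obj[name] = {"type": CONTINUOUS, "cutoffs": list(cuts)}
        for name, mapping in self.level_maps.items():
            obj[name] = {"type": CATEGORICAL, "level_map": dict(mapping)}
        return json.dumps(obj, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TransformSpec":
        obj = json.loads(text)
        cutoffs, level_maps = {}, {}
        for name, rule in obj.items():
            if rule["type"] == CONTINUOUS:
                cutoffs[name] = tuple(float(c) for c in rule["cutoffs"])
            else:
                level_maps[name] = dict(rule["level_map"])
        return cls(cutoffs=cutoffs, level_maps=level_maps)


def derive_transform_spec(
    train: CohortTable,
    variables: list[str],
    grid: QuantileGrid = QuantileGrid(),
) -> TransformSpec:
    """Build a TransformSpec for the selected variables from training data."""
    cutoffs: dict[str, tuple[float, ...]] = {}
    level_maps: dict[str, dict[str, str]] = {}
    for name in variables:
        if name not in train.var_kinds:
            raise ConfigurationError(f"unknown variable {name!r}")
        if train.var_kinds[name] == CONTINUOUS:
            cutoffs[name] = derive_cutoffs(train.data[name], grid)
        else:
            counts = train.data[name].astype(str).value_counts().to_dict()
            level_maps[name] = merge_categories(counts, grid.max_categories)
    return TransformSpec(cutoffs=cutoffs, level_maps=level_maps)


def apply_transform(cohort: CohortTable, spec: TransformSpec) -> pd.DataFrame:
    """Categorize every spec-covered variable; returns outcome + categories.

    Continuous columns become ordered pandas Categoricals over the bin
    labels.  A categorical level unseen at spec-derivation time maps to
    "Other" when the spec produced one, otherwise to the variable's most
    frequent mapped level (which releveling later treats like any other
    category).
    """
    for name in spec.variables:
        if name not in cohort.data.columns:
            raise ConfigurationError(f"spec variable {name!r} missing from cohort")
    out = pd.DataFrame(index=cohort.data.index)
    out[cohort.outcome] = cohort.data[cohort.outcome].to_numpy(dtype=int)
    for name, cuts in spec.cutoffs.items():
        labels = bin_labels(cuts)
        idx = np.searchsorted(
            np.asarray(cuts), cohort.data[name].to_numpy(dtype=float), side="right"
        )
        out[name] = pd.Categorical.from_codes(idx, categories=labels, ordered=True)
    for name, mapping in spec.level_maps.items():
        cats = spec.categories(name)
        fallback = OTHER_LEVEL if OTHER_LEVEL in cats else cats[0]
        mapped = cohort.data[name].astype(str).map(lambda lv: mapping.get(lv, fallback))
        out[name] = pd.Categorical(mapped, categories=cats, ordered=False)
    return out
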