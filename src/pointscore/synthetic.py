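"""Synthetic EHR-like cohorts with a known category-level risk structure.

The generator draws first-day-style predictors (vitals, labs,
demographics) from simple marginals and produces a binary outcome from a
TRUE point-based score: each variable has true cutoffs and true integer
category points, the per-row true total T feeds a logistic link,

    P(Y=1) = expit(intercept + slope * T + e),   e ~ N(0, noise_sd^2),

and missingness is injected completely at random.  Because the truth is
expressed in the same formalism the pipeline estimates (cutoffs + integer
points through a logistic link), parameter recovery is a well-posed test:
the fitted category coefficients converge to slope * true points.

The normal noise term e models unmeasured patient heterogeneity; it
attenuates all category effects by a common factor and so preserves the
true point ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import CATEGORICAL, CONTINUOUS, CohortTable
from .errors import ValidationError


@dataclass(frozen=True)
class VariableSpec:
    """Marginal distribution plus the variable's true risk contribution.

    ``dist`` is one of ``("normal", mu, sigma)``, ``("lognormal", mu,
    sigma)`` (log-scale parameters) or ``("categorical", levels, probs)``.
    Continuous variables carry true ``cutoffs`` (left-closed bins) and one
    integer point per bin; categorical ones carry one point per level.
    All-zero points make a pure-noise variable.
    """

    name: str
    kind: str
    dist: tuple
    cutoffs: tuple[float, ...] = ()
    points: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValidationError(f"unknown kind {self.kind!r}")
        if any(p < 0 or p != int(p) for p in self.points):
            raise ValidationError("true points must be nonnegative integers")
        if self.kind == CONTINUOUS:
            if list(self.cutoffs) != sorted(set(self.cutoffs)):
                raise ValidationError("cutoffs must be strictly increasing")
            if len(self.points) != len(self.cutoffs) + 1:
                raise ValidationError("need one point per bin (len(cutoffs)+1)")
        else:
            _, levels, probs = self.dist
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValidationError("level probabilities must sum to 1")
            if len(self.points) != len(levels):
                raise ValidationError("need one point per level")

    @property
    def is_signal(self) -> bool:
        return any(p > 0 for p in self.points)


@dataclass(frozen=True)
class GenerativeSpec:
    """Full recipe for one synthetic cohort."""

    n: int
    variables: tuple[VariableSpec, ...]
    intercept: float
    slope: float = 0.1
    noise_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    outcome: str = "death"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate variable names")


@dataclass(frozen=True)
class Truth:
    """Ground truth returned alongside a generated cohort."""

    cutoffs: dict[str, tuple[float, ...]]
    points: dict[str, dict[str, int]]
    true_totals: np.ndarray
    signal_variables: list[str]
    noise_variables: list[str]
    intercept: float
    slope: float


def _draw(var: VariableSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = var.dist[0]
    if kind == "normal":
        _, mu, sigma = var.dist
        return rng.normal(mu, sigma, size=n)
    if kind == "lognormal":
        _, mu, sigma = var.dist
        return rng.lognormal(mu, sigma, size=n)
    if kind == "categorical":
        _, levels, probs = var.dist
        return rng.choice(np.asarray(levels, dtype=object), size=n, p=probs)
    raise ValidationError(f"unknown distribution {kind!r}")


def _true_points_for(var: VariableSpec, values: np.ndarray) -> np.ndarray:
    if var.kind == CONTINUOUS:
        idx = np.searchsorted(np.asarray(var.cutoffs), values.astype(float), side="right")
        return np.asarray(var.points)[idx]
    _, levels, _ = var.dist
    lookup = {lv: p for lv, p in zip(levels, var.points)}
    return np.asarray([lookup[v] for v in values], dtype=int)


def generate_cohort(spec: GenerativeSpec) -> tuple[CohortTable, Truth]:
    """Draw a cohort and its ground truth; fully reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    values: dict[str, np.ndarray] = {}
    totals = np.zeros(spec.n, dtype=int)
    for var in spec.variables:
        v = _draw(var, spec.n, rng)
        values[var.name] = v
        totals += _true_points_for(var, v)
    eta = spec.intercept + spec.slope * totals
    if spec.noise_sd > 0:
        eta = eta + rng.normal(0.0, spec.noise_sd, size=spec.n)
    y = rng.binomial(1, expit(eta))

    df = pd.DataFrame(index=pd.RangeIndex(spec.n))
    df[spec.outcome] = y
    for var in spec.variables:
        col = pd.Series(values[var.name], index=df.index, dtype=object)
        if var.kind == CONTINUOUS:
            col = col.astype(float)
        if spec.missing_rate > 0:
            mask = rng.random(spec.n) < spec.missing_rate
            col = col.where(~mask, np.nan)
        df[var.name] = col

    cohort = CohortTable(
        data=df,
        outcome=spec.outcome,
        var_kinds={v.name: v.kind for v in spec.variables},
    )
    truth = Truth(
        cutoffs={v.name: v.cutoffs for v in spec.variables if v.kind == CONTINUOUS},
        points={
            v.name: (
                {lab: int(p) for lab, p in zip(_bin_names(v), v.points)}
                if v.kind == CONTINUOUS
                else {lv: int(p) for lv, p in zip(v.dist[1], v.points)}
            )
            for v in spec.variables
        },
        true_totals=totals,
        signal_variables=[v.name for v in spec.variables if v.is_signal],
        noise_variables=[v.name for v in spec.variables if not v.is_signal],
        intercept=spec.intercept,
        slope=spec.slope,
    )
    return cohort, truth


def _bin_names(var: VariableSpec) -> list[str]:
    from .transform import bin_labels

    return bin_labels(var.cutoffs)


def calibrate_intercept(
    variables: tuple[VariableSpec, ...],
    slope: float,
    noise_sd: float,
    target_prevalence: float,
    n_sim: int = 50_000,
    seed: int = 987_654,
) -> float:
    """Intercept giving the target event prevalence, by bisection.

    The expected prevalence E[expit(b + slope*T + e)] is monotone in b;
    it is estimated on one fixed simulated draw of true totals and noise
    so the root-find is deterministic.
    """
    rng = np.random.default_rng(seed)
    totals = np.zeros(n_sim, dtype=int)
    for var in variables:
        totals += _true_points_for(var, _draw(var, n_sim, rng))
    noise = rng.normal(0.0, noise_sd, size=n_sim) if noise_sd > 0 else 0.0

    def prevalence_gap(b: float) -> float:
        return float(expit(b + slope * totals + noise).mean()) - target_prevalence

    return float(brentq(prevalence_gap, -30.0, 30.0, xtol=1e-6))


def _default_variables() -> tuple[VariableSpec, ...]:
    """First-day ICU table: 9 signal vitals/labs, 10 noise labs, 2 categoricals.

    Marginals are plausible adult-ICU shapes (age in years, heart rate in
    beats/min, lactate in mmol/L, ...); cutoffs sit at conventional
    clinical boundaries and points grow with physiological derangement,
    U-shaped where both extremes are dangerous.
    """
    # every true bin keeps >= ~1.5% marginal mass and distinct points within
    # a variable differ by >= 3, so the category effects are estimable and
    # their ordering is statistically recoverable at the cohort sizes used
    signal = (
        VariableSpec("age", CONTINUOUS, ("normal", 63.0, 17.0),
                     cutoffs=(30, 48, 78, 85), points=(0, 4, 9, 14, 19)),
        VariableSpec("heart_rate", CONTINUOUS, ("normal", 87.0, 18.0),
                     cutoffs=(62, 72, 98, 112), points=(8, 0, 4, 12, 16)),
        VariableSpec("resp_rate", CONTINUOUS, ("normal", 19.0, 5.0),
                     cutoffs=(12, 16, 22), points=(8, 0, 4, 12)),
        VariableSpec("sbp", CONTINUOUS, ("normal", 120.0, 23.0),
                     cutoffs=(90, 100, 130, 150), points=(16, 8, 0, 4, 12)),
        VariableSpec("temperature", CONTINUOUS, ("normal", 36.9, 0.8),
                     cutoffs=(36, 36.5, 37.5, 38), points=(12, 4, 0, 8, 16)),
        VariableSpec("spo2", CONTINUOUS, ("normal", 94.5, 4.5),
                     cutoffs=(85, 90, 95), points=(16, 10, 5, 0)),
        VariableSpec("platelet", CONTINUOUS, ("lognormal", 5.35, 0.45),
                     cutoffs=(80, 150, 300, 450), points=(16, 4, 0, 8, 12)),
        VariableSpec("bun", CONTINUOUS, ("lognormal", 2.95, 0.60),
                     cutoffs=(7.5, 12, 35, 70), points=(0, 4, 8, 12, 16)),
        VariableSpec("lactate", CONTINUOUS, ("lognormal", 0.65, 0.45),
                     cutoffs=(1, 2.5, 4), points=(0, 5, 10, 15)),
    )
    noise_specs = (
        ("hematocrit", ("normal", 32.5, 5.5)),
        ("hemoglobin", ("normal", 10.9, 1.9)),
        ("wbc", ("lognormal", 2.35, 0.40)),
        ("sodium", ("normal", 139.0, 4.5)),
        ("potassium", ("normal", 4.1, 0.55)),
        ("chloride", ("normal", 104.0, 5.5)),
        ("bicarbonate", ("normal", 24.0, 4.2)),
        ("creatinine", ("lognormal", 0.05, 0.50)),
        ("glucose", ("lognormal", 4.85, 0.30)),
        ("magnesium", ("normal", 2.0, 0.3)),
    )
    noise = tuple(
        VariableSpec(name, CONTINUOUS, dist,
                     cutoffs=(0.0,), points=(0, 0))
        for name, dist in noise_specs
    )
    categorical = (
        VariableSpec("sex", CATEGORICAL,
                     ("categorical", ("female", "male"), (0.43, 0.57)),
                     points=(0, 4)),
        VariableSpec("admission_type", CATEGORICAL,
                     ("categorical", ("elective", "emergency", "urgent"),
                      (0.12, 0.85, 0.03)),
                     points=(0, 6, 3)),
    )
    return signal + noise + categorical


_DEFAULT_SLOPE = 0.15
_DEFAULT_NOISE_SD = 0.5
_DEFAULT_PREVALENCE = 0.09


def default_ehr_spec(
    n: int = 44_918, seed: int = 0, missing_rate: float = 0.02
) -> GenerativeSpec:
    """The standard test-bed cohort: ICU-like first-day table, ~9% mortality.

    Nine continuous signal variables, ten pure-noise labs and two weakly
    informative categoricals; the intercept is calibrated by bisection so
    the event prevalence lands near 9%.
    """
    variables = _default_variables()
    intercept = calibrate_intercept(
        variables, _DEFAULT_SLOPE, _DEFAULT_NOISE_SD, _DEFAULT_PREVALENCE
    )
    return GenerativeSpec(
        n=n,
        variables=variables,
        intercept=intercept,
        slope=_DEFAULT_SLOPE,
        noise_sd=_DEFAULT_NOISE_SD,
        missing_rate=missing_rate,
        seed=seed,
    )


def spec_from_dict(obj: dict) -> GenerativeSpec:
    """Build a GenerativeSpec from a plain dict (YAML/JSON config).

    Expected layout::

        n: 10000
        seed: 0
        slope: 0.15          # optional, default 0.15
        noise_sd: 0.5        # optional
        missing_rate: 0.02   # optional
        intercept: -6.3      # optional; omit to calibrate to `prevalence`
        prevalence: 0.09     # used only when intercept is omitted
        variables:
          - {name: age, kind: continuous, dist: [normal, 63, 17],
             cutoffs: [30, 48, 78, 85], points: [0, 4, 9, 14, 19]}
          - {name: sex, kind: categorical,
             dist: [categorical, [female, male], [0.43, 0.57]], points: [0, 4]}
    """
    variables = []
    for v in obj["variables"]:
        dist = v["dist"]
        if dist[0] == "categorical":
            dist = (dist[0], tuple(dist[1]), tuple(float(p) for p in dist[2]))
        else:
            dist = (dist[0], float(dist[1]), float(dist[2]))
        variables.append(
            VariableSpec(
                name=v["name"],
                kind=v["kind"],
                dist=dist,
                cutoffs=tuple(float(c) for c in v.get("cutoffs", ())),
                points=tuple(int(p) for p in v.get("points", ())),
            )
        )
    variables = tuple(variables)
    slope = float(obj.get("slope", _DEFAULT_SLOPE))
    noise_sd = float(obj.get("noise_sd", 0.0))
    if "intercept" in obj and obj["intercept"] is not None:
        intercept = float(obj["intercept"])
    else:
        intercept = calibrate_intercept(
            variables, slope, noise_sd, float(obj.get("prevalence", 0.09))
        )
    return GenerativeSpec(
        n=int(obj["n"]),
        variables=variables,
        intercept=intercept,
        slope=slope,
        noise_sd=noise_sd,
        missing_rate=float(obj.get("missing_rate", 0.0)),
        seed=int(obj.get("seed", 0)),
        outcome=obj.get("outcome", "death"),
    )


def simple_spec(
    n: int,
    n_signal: int = 3,
    n_noise: int = 7,
    seed: int = 0,
    slope: float = 0.35,
    noise_sd: float = 0.0,
    prevalence: float = 0.2,
) -> GenerativeSpec:
    """Small generic cohort: standard-normal signal + noise variables.

    Signal variable i has cutoffs at (-1, 0, 1) and monotone points
    (0, 1, 2, 4); useful for plateau and oracle tests where the EHR
    dressing is irrelevant.
    """
    variables = tuple(
        VariableSpec(f"x{i + 1:02d}", CONTINUOUS, ("normal", 0.0, 1.0),
                     cutoffs=(-1.0, 0.0, 1.0), points=(0, 1, 2, 4))
        for i in range(n_signal)
    ) + tuple(
        VariableSpec(f"z{i + 1:02d}", CONTINUOUS, ("normal", 0.0, 1.0),
                     cutoffs=(0.0,), points=(0, 0))
        for i in range(n_noise)
    )
    intercept = calibrate_intercept(variables, slope, noise_sd, prevalence)
    return GenerativeSpec(
        n=n,
        variables=variables,
        intercept=intercept,
        slope=slope,
        noise_sd=noise_sd,
        seed=seed,
    )
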