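"""End-to-end risk-score derivation as a model/results pair.

:class:`RiskScoreModel` is built from a cohort table and configuration;
``fit()`` runs the whole derivation — clean, split, impute, rank,
parsimony search, transform, weight fitting, point conversion — and
returns a :class:`RiskScoreResults` carrying the score table, the
diagnostics and the held-out test evaluation, with ``summary()``,
``predict()``, plotting and artifact persistence attached.

The test partition is touched exactly once, in the final evaluation:
ranking, binning, weighting and model-size selection see only the
training and validation partitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortTable,
    PlausibilityRanges,
    SplitSpec,
    flag_outliers,
    impute_from_training,
    split_cohort,
)
from .evaluation import EvalReport, evaluate_scores
from .ranking import RFConfig, VariableRanking, rank_variables
from .score import ScoreTable, normalize_to_ceiling, score_episodes
from .selection import (
    ParsimonyCurve,
    SelectionPolicy,
    derive_score_for_variables,
    fine_tune_cutoffs,
    parsimony_curve,
    select_m,
)
from .transform import QuantileGrid, TransformSpec, apply_transform

# fixed offsets fan the global seed out to the stochastic stages, so each
# stage is individually reproducible from the one seed in the run log
_SPLIT_OFFSET = 11
_RF_OFFSET = 23
_BOOT_OFFSET = 37
_SEED_MOD = 2**31 - 1


class RiskScoreModel:
    """Derives an integer point-based risk score from a cohort table.

    Parameters
    ----------
    cohort : CohortTable
        The full cohort (see :func:`pointscore.load_cohort` /
        :meth:`from_dataframe`).
    ranges : PlausibilityRanges, optional
        Physical plausibility bounds; out-of-range values become missing
        before the split.
    split, rf, grid, policy
        Stage configurations; when omitted, defaults are used with seeds
        fanned out from ``seed``.
    ceiling : int, optional
        Normalize the final score so its maximum total is about this.
    bootstrap_reps : int
        Replicates for every bootstrap confidence interval.
    seed : int
        Global seed; propagates deterministically to every stage.
    """

    def __init__(
        self,
        cohort: CohortTable,
        ranges: PlausibilityRanges | None = None,
        split: SplitSpec | None = None,
        rf: RFConfig | None = None,
        grid: QuantileGrid | None = None,
        policy: SelectionPolicy | None = None,
        ceiling: int | None = None,
        bootstrap_reps: int = 1000,
        seed: int = 0,
    ) -> None:
        self.cohort = cohort
        self.ranges = ranges
        self.seed = int(seed)
        self.split = split or SplitSpec(seed=(self.seed + _SPLIT_OFFSET) % _SEED_MOD)
        self.rf = rf or RFConfig(seed=(self.seed + _RF_OFFSET) % _SEED_MOD)
        self.grid = grid or QuantileGrid()
        self.policy = policy or SelectionPolicy()
        self.ceiling = ceiling
        self.bootstrap_reps = int(bootstrap_reps)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        var_kinds: dict[str, str] | None = None,
        **kwargs,
    ) -> "RiskScoreModel":
        """Build a model straight from a DataFrame, inferring variable kinds.

        Numeric columns are treated as continuous, everything else as
        categorical; pass ``var_kinds`` to override.
        """
        if var_kinds is None:
            var_kinds = {
                c: ("continuous" if pd.api.types.is_numeric_dtype(data[c]) else "categorical")
                for c in data.columns
                if c != outcome
            }
        cohort = CohortTable(data=data, outcome=outcome, var_kinds=var_kinds)
        return cls(cohort, **kwargs)

    def fit(
        self, m: int | None = None, m_values: list[int] | None = None
    ) -> "RiskScoreResults":
        """Run the full derivation and return the results object.

        ``m`` forces the number of variables (the human-in-the-loop
        choice); otherwise the selection policy picks it from the
        parsimony curve.
        """
        cohort = self.cohort
        if self.ranges is not None:
            cohort = flag_outliers(cohort, self.ranges)
        train, validation, test = split_cohort(cohort, self.split)
        train, (validation, test) = impute_from_training(train, [validation, test])

        ranking = rank_variables(train, self.rf)
        if m_values is None:
            m_values = list(range(1, min(self.policy.m_max, len(ranking)) + 1))
        curve = parsimony_curve(train, validation, ranking, self.grid, m_values)
        if m is not None:
            policy = SelectionPolicy(mode="manual", manual_m=int(m), delta=self.policy.delta)
        else:
            policy = self.policy
        m_star = select_m(curve, policy)

        spec, table = derive_score_for_variables(train, ranking.top(m_star), self.grid)
        if self.ceiling is not None:
            table = normalize_to_ceiling(table, self.ceiling)

        medians = {
            v: float(train.data[v].median()) for v in train.continuous_variables()
        }
        report = self._evaluate(test, spec, table)
        return RiskScoreResults(
            model=self,
            ranking=ranking,
            parsimony=curve,
            m=m_star,
            transform_spec=spec,
            score_table=table,
            eval_report=report,
            train=train,
            validation=validation,
            test=test,
            train_medians=medians,
        )

    def _evaluate(
        self, test: CohortTable, spec: TransformSpec, table: ScoreTable
    ) -> EvalReport:
        test_cat = apply_transform(test, spec)
        scores = score_episodes(test_cat, table)
        return evaluate_scores(
            scores,
            test.y,
            reps=self.bootstrap_reps,
            seed=(self.seed + _BOOT_OFFSET) % _SEED_MOD,
        )


@dataclass
class RiskScoreResults:
    """Everything the derivation produced, plus reporting helpers."""

    model: RiskScoreModel
    ranking: VariableRanking
    parsimony: ParsimonyCurve
    m: int
    transform_spec: TransformSpec
    score_table: ScoreTable
    eval_report: EvalReport
    train: CohortTable
    validation: CohortTable
    test: CohortTable
    train_medians: dict[str, float]

    @property
    def variables(self) -> list[str]:
        return self.score_table.variables

    def predict(self, data: CohortTable | pd.DataFrame) -> np.ndarray:
        """Integer scores for new episodes.

        Missing continuous values are imputed with the training medians;
        missing categoricals score as their variable's fallback category.
        """
        df = data.data.copy() if isinstance(data, CohortTable) else data.copy()
        for var, med in self.train_medians.items():
            if var in df.columns:
                df[var] = pd.to_numeric(df[var], errors="coerce").fillna(med)
        outcome = self.model.cohort.outcome
        if outcome not in df.columns:
            df[outcome] = 0  # placeholder; transform carries the outcome through
        needed = self.transform_spec.variables
        cohort = CohortTable(
            data=df[[outcome] + needed],
            outcome=outcome,
            var_kinds={v: self.model.cohort.var_kinds[v] for v in needed},
        )
        cat = apply_transform(cohort, self.transform_spec)
        return score_episodes(cat, self.score_table)

    def refine(self, overrides: dict[str, list[float]]) -> "RiskScoreResults":
        """Re-derive the score after hand-tuning cutoffs.

        Applies the overrides to the transform spec, re-runs binning and
        weight fitting on the stored training partition, and re-evaluates
        on the test partition.  Returns a new results object.
        """
        spec = fine_tune_cutoffs(self.transform_spec, overrides)
        spec, table = derive_score_for_variables(
            self.train, spec.variables, self.model.grid, spec=spec
        )
        if self.model.ceiling is not None:
            table = normalize_to_ceiling(table, self.model.ceiling)
        report = self.model._evaluate(self.test, spec, table)
        return RiskScoreResults(
            model=self.model,
            ranking=self.ranking,
            parsimony=self.parsimony,
            m=self.m,
            transform_spec=spec,
            score_table=table,
            eval_report=report,
            train=self.train,
            validation=self.validation,
            test=self.test,
            train_medians=self.train_medians,
        )

    def summary(self) -> str:
        """Human-readable account of the derived score and its performance."""
        t = self.score_table
        r = self.eval_report
        lines = [
            "Point-based risk score derivation results",
            "=" * 57,
            f"episodes: {self.model.cohort.n}  "
            f"(train {self.train.n} / val {self.validation.n} / test {self.test.n})",
            f"outcome: {self.model.cohort.outcome}  "
            f"(test prevalence {100 * r.prevalence:.1f}%)",
            f"variables: {self.m} of {len(self.ranking)} candidates "
            f"(selected on the validation parsimony curve)",
            f"total score range: {t.min_total} to {t.max_total}"
            + (f" (ceiling {t.ceiling})" if t.ceiling else ""),
            "",
            "Score table",
            "-" * 57,
        ]
        for var in t.variables:
            lines.append(f"  {var}")
            for cat in t._ordered_cats(var):
                lines.append(f"    {cat:<24s} {t.points[var][cat]:>4d}")
        lines += [
            "",
            "Test-set performance (positive iff score >= threshold)",
            "-" * 57,
            f"  AUC {r.auc:.3f} (95% CI {r.auc_ci[0]:.3f}-{r.auc_ci[1]:.3f})",
        ]
        for mrow in r.thresholds:
            lines.append(
                f"  {mrow.label:<16s} threshold {mrow.threshold:g}: "
                f"sens {100 * mrow.sensitivity:.1f}%  spec {100 * mrow.specificity:.1f}%  "
                f"ppv {100 * mrow.ppv:.1f}%  npv {100 * mrow.npv:.1f}%"
            )
        return "\n".join(lines)

    # ---------------------------------------------------------------- plots

    def plot_parsimony(self, ax=None):
        """Validation AUC versus number of variables."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        df = self.parsimony.to_dataframe()
        ax.plot(df["m"], df["auc"], marker="o")
        ax.axvline(self.m, color="grey", linestyle="--", linewidth=1)
        ax.set_xlabel("number of variables (m)")
        ax.set_ylabel("validation AUC")
        ax.set_title("Parsimony curve")
        return ax

    def plot_calibration(self, ax=None):
        """Observed event rate per score interval on the test set."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        calib = self.eval_report.calibration
        ax.bar(range(len(calib)), 100 * calib["observed_rate"], tick_label=calib["interval"])
        ax.set_xlabel("score interval")
        ax.set_ylabel("observed event rate (%)")
        ax.tick_params(axis="x", rotation=60)
        ax.set_title("Score-bin calibration")
        return ax

    # ------------------------------------------------------------ artifacts

    def save_artifacts(self, outdir) -> dict[str, Path]:
        """Persist every derivation artifact; returns name -> path."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def write(name: str, text: str) -> None:
            p = out / name
            p.write_text(text)
            paths[name] = p

        write("ranking.json", json.dumps(self.ranking.to_records(), indent=2))
        self.parsimony.to_dataframe().to_csv(out / "parsimony.csv", index=False)
        paths["parsimony.csv"] = out / "parsimony.csv"
        write("transform_spec.json", self.transform_spec.to_json())
        write("score_table.json", self.score_table.to_json())
        write("score_table.md", self.score_table.to_markdown())
        self.eval_report.to_dataframe().to_csv(out / "eval_report.csv", index=False)
        paths["eval_report.csv"] = out / "eval_report.csv"
        write("eval_report.md", self.eval_report.to_markdown())
        self.eval_report.calibration.to_csv(out / "calibration.csv", index=False)
        paths["calibration.csv"] = out / "calibration.csv"
        write(
            "run.json",
            json.dumps(
                {
                    "package_version": __version__,
                    "seed": self.model.seed,
                    "split": list(self.model.split.fractions),
                    "n_trees": self.model.rf.n_trees,
                    "quantiles": list(self.model.grid.percentiles),
                    "m": self.m,
                    "ceiling": self.model.ceiling,
                    "bootstrap_reps": self.model.bootstrap_reps,
                },
                indent=2,
            ),
        )
        try:
            import matplotlib

            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            ax = self.plot_parsimony()
            ax.figure.savefig(out / "parsimony.png", dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
            ax = self.plot_calibration()
            ax.figure.savefig(out / "calibration.png", dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
            paths["parsimony.png"] = out / "parsimony.png"
            paths["calibration.png"] = out / "calibration.png"
        except Exception:  # plotting must never fail a run
            pass
        return paths


def evaluate_saved_score(
    score_table_json: str | Path,
    transform_spec_json: str | Path,
    cohort: CohortTable,
    reps: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Evaluate a persisted score table on a cohort.

    The serialized score table plus transform spec are the complete
    deployable object; re-running evaluation from them reproduces the
    report exactly.
    """
    table = ScoreTable.from_json(Path(score_table_json).read_text())
    spec = TransformSpec.from_json(Path(transform_spec_json).read_text())
    cat = apply_transform(cohort, spec)
    scores = score_episodes(cat, table)
    return evaluate_scores(scores, cohort.y, reps=reps, seed=seed)
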