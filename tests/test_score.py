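"""Logistic weight fitting, releveling, point conversion and scoring."""

import math

import numpy as np
import pandas as pd
import pytest

import pointscore as ps
from pointscore.errors import DegenerateOutcomeError, NoSignalError, ScoringError, ValidationError
from pointscore.examples import inpatient_mortality_example
from pointscore.score import (
    WeightFit,
    linear_predictor,
    prerounding_scores,
    round_half_away_from_zero,
)
from pointscore.transform import apply_transform, derive_transform_spec


def two_by_two_table(n_exposed=500, n_unexposed=500, rate_exposed=0.8, rate_unexposed=0.2):
    """Deterministic 2x2 cohort with exact category event counts."""
    rows = []
    for cat, n, rate in (("exposed", n_exposed, rate_exposed),
                         ("unexposed", n_unexposed, rate_unexposed)):
        k = int(round(n * rate))
        rows += [{"exposure": cat, "death": 1}] * k
        rows += [{"exposure": cat, "death": 0}] * (n - k)
    return pd.DataFrame(rows)


class TestFitWeights:
    def test_recovers_log_odds_ratio_of_2x2_table(self):
        df = two_by_two_table()
        fit = ps.fit_weights(df, ["exposure"], "death", references={"exposure": "unexposed"})
        beta = fit.coefs["exposure"]["exposed"]
        assert abs(beta - math.log(16)) < 0.05

    def test_null_predictor_has_near_zero_coefficient(self):
        df = two_by_two_table(rate_exposed=0.3, rate_unexposed=0.3)
        fit = ps.fit_weights(df, ["exposure"], "death", references={"exposure": "unexposed"})
        assert abs(fit.coefs["exposure"]["exposed"]) < 0.05

    def test_zero_event_category_is_finite_and_flagged(self):
        df = two_by_two_table(rate_exposed=0.5, rate_unexposed=0.0)
        fit = ps.fit_weights(df, ["exposure"], "death", references={"exposure": "unexposed"})
        assert np.isfinite(fit.coefs["exposure"]["exposed"])
        assert fit.separation

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"exposure": ["a", "b"], "death": [0, 0]})
        with pytest.raises(DegenerateOutcomeError):
            ps.fit_weights(df, ["exposure"], "death")


class TestRelevelReferences:
    def cohort_cat(self, seed=0, n=3000):
        spec = ps.simple_spec(n=n, n_signal=2, n_noise=1, seed=seed)
        cohort, _ = ps.generate_cohort(spec)
        tspec = derive_transform_spec(cohort, cohort.predictors)
        return apply_transform(cohort, tspec), tspec

    def test_new_reference_is_lowest_first_pass_category(self):
        cat, tspec = self.cohort_cat()
        fit = ps.fit_weights(cat, tspec.variables, "death")
        for var in fit.variables:
            coefs = {c: fit.coefficient(var, c) for c in fit.categories[var]}
            expected_ref = min(fit.categories[var], key=lambda c: coefs[c])
            releveled = ps.relevel_references(fit, cat, "death")
            assert releveled.references[var] == expected_ref

    def test_second_pass_coefficients_nonnegative(self):
        cat, tspec = self.cohort_cat(seed=5)
        fit = ps.fit_weights(cat, tspec.variables, "death")
        releveled = ps.relevel_references(fit, cat, "death")
        for var, d in releveled.coefs.items():
            assert all(b >= 0 for b in d.values())

    def test_fixed_point_when_reference_already_lowest(self):
        df = two_by_two_table()
        fit = ps.fit_weights(df, ["exposure"], "death", references={"exposure": "unexposed"})
        releveled = ps.relevel_references(fit, df, "death")
        assert releveled.references == {"exposure": "unexposed"}
        assert releveled.coefs["exposure"]["exposed"] == pytest.approx(
            fit.coefs["exposure"]["exposed"], abs=1e-6
        )

    def test_clamped_values_keep_raw_copy(self):
        fit = WeightFit(
            intercept=-1.0,
            coefs={"x": {"b": 0.0, "c": 0.5}},
            raw_coefs={"x": {"b": -0.02, "c": 0.5}},
            references={"x": "a"},
            categories={"x": ["a", "b", "c"]},
        )
        assert fit.coefficient("x", "b") == 0.0
        assert fit.coefficient("x", "b", raw=True) == -0.02


def make_fit(coefs, categories=None):
    """Hand-built releveled fit for point-conversion tests."""
    cats = categories or {
        var: ["ref"] + sorted(d) for var, d in coefs.items()
    }
    return WeightFit(
        intercept=0.0,
        coefs=coefs,
        raw_coefs=coefs,
        references={var: cats[var][0] for var in coefs},
        categories=cats,
    )


class TestDerivePoints:
    def test_divide_by_lowest_and_round(self):
        fit = make_fit({"A": {"A2": 0.5, "A3": 1.0}, "B": {"B2": 0.25}})
        table = ps.derive_points(fit)
        assert table.points["A"]["A2"] == 2
        assert table.points["A"]["A3"] == 4
        assert table.points["B"]["B2"] == 1
        assert table.points["A"]["ref"] == 0

    def test_equal_coefficients_all_score_one(self):
        fit = make_fit({"A": {"A2": 0.7}, "B": {"B2": 0.7}})
        table = ps.derive_points(fit)
        assert table.points["A"]["A2"] == table.points["B"]["B2"] == 1

    def test_rounding_to_nearest(self):
        fit = make_fit({"A": {"A2": 0.37}, "B": {"B2": 0.25}})
        assert ps.derive_points(fit).points["A"]["A2"] == 1  # round(1.48)

    def test_all_zero_coefficients_is_no_signal(self):
        fit = make_fit({"A": {"A2": 0.0}, "B": {"B2": 1e-9}})
        with pytest.raises(NoSignalError):
            ps.derive_points(fit)

    def test_totals_sum_per_variable_extremes(self):
        fit = make_fit({"A": {"A2": 0.5, "A3": 1.0}, "B": {"B2": 0.25}})
        table = ps.derive_points(fit)
        assert table.min_total == 0
        assert table.max_total == 4 + 1

    @pytest.mark.parametrize(
        "x, expected", [(2.5, 3), (1.48, 1), (0.5, 1), (-2.5, -3), (0.49, 0)]
    )
    def test_round_half_away_from_zero(self, x, expected):
        assert round_half_away_from_zero(x) == expected


class TestNormalizeToCeiling:
    def test_halving_scales_every_point(self):
        fit = make_fit({"A": {"A2": 0.5, "A3": 1.5}, "B": {"B2": 0.25}})
        table = ps.derive_points(fit)  # points 2, 6, 1 -> max_total 8
        half = ps.normalize_to_ceiling(table, 4)
        assert half.points["A"]["A2"] == 1
        assert half.points["A"]["A3"] == 3
        assert half.points["B"]["B2"] == 1  # 0.5 rounds away from zero
        assert half.ceiling == 4

    def test_ceiling_equal_to_max_total_is_identity(self):
        fit = make_fit({"A": {"A2": 0.5, "A3": 1.0}, "B": {"B2": 0.25}})
        table = ps.derive_points(fit)
        same = ps.normalize_to_ceiling(table, table.max_total)
        assert same.points == table.points

    def test_single_variable_collapse(self):
        fit = make_fit({"A": {"A2": 1.0}})
        table = ps.normalize_to_ceiling(
            ps.derive_points(make_fit({"A": {"A2": 10.0, "A1b": 1.0}})), 1
        )
        assert max(table.points["A"].values()) == 1

    def test_ceiling_below_variable_count_rejected(self):
        fit = make_fit({"A": {"A2": 0.5}, "B": {"B2": 0.25}, "C": {"C2": 0.25}})
        with pytest.raises(ValidationError):
            ps.normalize_to_ceiling(ps.derive_points(fit), 2)

    def test_references_stay_zero(self):
        fit = make_fit({"A": {"A2": 0.5, "A3": 1.0}, "B": {"B2": 0.25}})
        table = ps.normalize_to_ceiling(ps.derive_points(fit), 3)
        assert table.points["A"]["ref"] == 0
        assert table.points["B"]["ref"] == 0


class TestComputeScore:
    def test_published_table_single_lookup(self):
        table, cutoffs = inpatient_mortality_example()
        age_cat = ps.categorize_continuous(50, cutoffs["age"])
        assert table.points["age"][age_cat] == 14

    def test_published_table_nine_variable_episode(self):
        table, cutoffs = inpatient_mortality_example()
        raw = {
            "age": 50, "heart_rate": 80, "resp_rate": 18, "sbp": 120,
            "temperature": 37.0, "spo2": 97, "platelet": 200, "bun": 20,
            "lactate": 1.5,
        }
        episode = {
            var: ps.categorize_continuous(val, cutoffs[var]) for var, val in raw.items()
        }
        assert ps.compute_score(episode, table) == 30

    def test_all_reference_episode_scores_zero(self):
        table, _ = inpatient_mortality_example()
        episode = {var: table.references[var] for var in table.variables}
        assert ps.compute_score(episode, table) == 0

    def test_missing_variable_is_scoring_error(self):
        table, _ = inpatient_mortality_example()
        with pytest.raises(ScoringError):
            ps.compute_score({"age": "<30"}, table)

    def test_random_episode_totals_respect_bounds(self):
        table, _ = inpatient_mortality_example()
        rng = np.random.default_rng(0)
        cats = {var: list(table.points[var]) for var in table.variables}
        for _ in range(10_000 // 100):
            batch = pd.DataFrame(
                {var: rng.choice(cats[var], size=100) for var in table.variables}
            )
            totals = ps.score_episodes(batch, table)
            assert (totals >= table.min_total).all()
            assert (totals <= table.max_total).all()

    def test_score_table_json_roundtrip(self):
        table, _ = inpatient_mortality_example()
        back = ps.ScoreTable.from_json(table.to_json())
        assert back.points == table.points
        assert back.min_total == table.min_total
        assert back.max_total == table.max_total


class TestMonotoneScoreOracle:
    def test_prerounding_score_is_affine_in_linear_predictor(self):
        spec = ps.simple_spec(n=2000, n_signal=3, n_noise=2, seed=17)
        cohort, _ = ps.generate_cohort(spec)
        tspec = derive_transform_spec(cohort, cohort.predictors)
        cat = apply_transform(cohort, tspec)
        fit = ps.fit_weights(cat, tspec.variables, "death")
        fit = ps.relevel_references(fit, cat, "death")
        lp = linear_predictor(cat, fit)
        pre = prerounding_scores(cat, fit)
        slope, icpt = np.polyfit(lp, pre, 1)
        np.testing.assert_allclose(pre, slope * lp + icpt, atol=1e-8)

    def test_integer_rounding_degrades_auc_mildly(self):
        spec = ps.simple_spec(n=5000, n_signal=3, n_noise=2, seed=23)
        cohort, _ = ps.generate_cohort(spec)
        tspec = derive_transform_spec(cohort, cohort.predictors)
        cat = apply_transform(cohort, tspec)
        fit = ps.relevel_references(
            ps.fit_weights(cat, tspec.variables, "death"), cat, "death"
        )
        table = ps.derive_points(fit)
        auc_int = ps.roc_auc(ps.score_episodes(cat, table), cohort.y)
        auc_pre = ps.roc_auc(prerounding_scores(cat, fit), cohort.y)
        assert abs(auc_int - auc_pre) < 0.02
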