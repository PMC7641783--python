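"""ROC/AUC, operating points, bootstrap intervals and calibration bins."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pointscore as ps
from pointscore.errors import CIError, DegenerateOutcomeError, UnattainableTargetError


def brute_force_auc(scores, labels):
    """Mean over all case-control pairs of 1/0.5/0 for win/tie/loss."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    cases, controls = s[y == 1], s[y == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ((1, 2, 3, 4), (0, 0, 1, 1), 1.0),
            ((1, 2, 3, 4), (1, 1, 0, 0), 0.0),
            ((1, 2, 3, 4), (0, 1, 0, 1), 0.75),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert ps.roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 30)
            scores = rng.integers(0, 8, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 0, 1
            assert ps.roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.normal(size=500) + np.repeat([0, 1], 250)
        labels = np.repeat([0, 1], 250)
        assert ps.roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.integers(0, 20), min_size=4, max_size=25),
        st.floats(0.1, 5.0),
        st.floats(-3.0, 3.0),
    )
    def test_invariant_under_increasing_transform(self, scores, a, b):
        labels = [i % 2 for i in range(len(scores))]
        s = np.asarray(scores, dtype=float)
        transformed = np.exp(a * s) + b  # strictly increasing
        assert ps.roc_auc(s, labels) == pytest.approx(
            ps.roc_auc(transformed, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            ps.roc_auc((1, 2), (1, 1))


class TestOptimalThreshold:
    def test_perfect_separation_returns_lowest_zero_distance(self):
        assert ps.optimal_threshold((1, 2, 10, 11), (0, 0, 1, 1)) == 10

    def test_tie_resolved_to_lowest_threshold(self):
        # thresholds 2 and 4 both sit at distance 0.5; the lower wins
        assert ps.optimal_threshold((1, 2, 3, 4), (0, 1, 0, 1)) == 2

    def test_single_distinct_score(self):
        assert ps.optimal_threshold((5, 5, 5, 5), (0, 1, 0, 1)) == 5

    def test_enumeration_oracle_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = rng.integers(0, 10, size=30).astype(float)
            y = rng.integers(0, 2, size=30)
            if y.sum() in (0, 30):
                continue
            t = ps.optimal_threshold(s, y)
            dist = lambda th: np.hypot(
                1 - ps.confusion_metrics(s, y, th).sensitivity,
                1 - ps.confusion_metrics(s, y, th).specificity,
            )
            best = min(dist(th) for th in np.unique(s))
            assert dist(t) == pytest.approx(best, abs=1e-12)


class TestThresholdForTarget:
    S = (10, 20, 30, 40)
    Y = (0, 0, 1, 1)

    def test_sensitivity_target_takes_largest_feasible_threshold(self):
        m = ps.threshold_for_target(self.S, self.Y, "sensitivity", 0.95)
        assert m.threshold == 30
        assert m.sensitivity == 1.0

    def test_specificity_target_takes_smallest_feasible_threshold(self):
        m = ps.threshold_for_target(self.S, self.Y, "specificity", 0.95)
        assert m.threshold == 30
        assert m.specificity == 1.0

    def test_level_zero_sensitivity_boundary(self):
        m = ps.threshold_for_target(self.S, self.Y, "sensitivity", 0.0)
        assert m.threshold == 40  # highest threshold still satisfies sens >= 0

    def test_unattainable_level_rejected(self):
        # scores identical: sens and spec cannot both be driven high
        with pytest.raises(UnattainableTargetError):
            ps.threshold_for_target((5, 5, 5, 5), (0, 0, 1, 1), "specificity", 0.95)


class TestConfusionMetrics:
    def test_clean_split(self):
        m = ps.confusion_metrics((10, 20, 30, 40), (0, 0, 1, 1), 25)
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_threshold_above_max_gives_undefined_ppv(self):
        m = ps.confusion_metrics((10, 20, 30, 40), (0, 0, 1, 1), 99)
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0
        assert np.isnan(m.ppv)

    def test_threshold_below_min_gives_undefined_npv(self):
        m = ps.confusion_metrics((10, 20, 30, 40), (0, 0, 1, 1), 5)
        assert m.sensitivity == 1.0
        assert m.specificity == 0.0
        assert np.isnan(m.npv)

    def test_predicted_positive_accounting(self):
        rng = np.random.default_rng(4)
        s = rng.integers(0, 15, size=200).astype(float)
        y = rng.integers(0, 2, size=200)
        P, N = y.sum(), (1 - y).sum()
        for t in np.unique(s):
            m = ps.confusion_metrics(s, y, t)
            predicted_pos = m.sensitivity * P + (1 - m.specificity) * N
            assert predicted_pos == pytest.approx((s >= t).sum(), abs=1e-9)


class TestBootstrapCI:
    def test_degenerate_metric_gives_point_interval(self):
        s = np.r_[np.zeros(50), np.ones(50)]
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        assert ps.bootstrap_ci(ps.roc_auc, s, y, reps=200, seed=0) == (1.0, 1.0)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=300)
        y = rng.integers(0, 2, size=300)
        a = ps.bootstrap_ci(ps.roc_auc, s, y, reps=200, seed=9)
        b = ps.bootstrap_ci(ps.roc_auc, s, y, reps=200, seed=9)
        assert a == b

    def test_interval_covers_point_estimate_on_synthetic_auc(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=500)
        s = rng.normal(size=500) + 0.95 * y  # true AUC ~ 0.75
        point = ps.roc_auc(s, y)
        low, high = ps.bootstrap_ci(ps.roc_auc, s, y, reps=400, seed=1)
        assert low <= point <= high
        assert 0.65 < point < 0.85

    def test_mostly_undefined_metric_is_ci_error(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=100)
        y = rng.integers(0, 2, size=100)
        with pytest.raises(CIError):
            ps.bootstrap_ci(lambda s_, y_: float("nan"), s, y, reps=100, seed=0)


class TestCalibrationBins:
    def test_single_bin_recovers_overall_rate(self):
        calib = ps.calibration_bins((1, 2, 3, 4), (0, 1, 0, 1), edges=(0, 10))
        assert len(calib) == 1
        assert calib["n"].iloc[0] == 4
        assert calib["observed_rate"].iloc[0] == 0.5

    def test_counts_conserve_n_even_with_outliers(self):
        scores = (-5, 1, 2, 3, 99)
        calib = ps.calibration_bins(scores, (0, 0, 1, 0, 1), edges=(0, 2, 4))
        assert calib["n"].sum() == 5

    def test_empty_bin_reports_nan_rate(self):
        calib = ps.calibration_bins((1, 1, 9, 9), (0, 1, 0, 1), edges=(0, 3, 6, 10))
        middle = calib.iloc[1]
        assert middle["n"] == 0
        assert np.isnan(middle["observed_rate"])

    def test_generative_score_rates_increase_across_bins(self):
        spec = ps.simple_spec(n=8000, n_signal=3, n_noise=0, seed=21)
        cohort, truth = ps.generate_cohort(spec)
        calib = ps.calibration_bins(
            truth.true_totals, cohort.y, edges=np.arange(0, 14, 2)
        )
        occupied = calib[calib["n"] > 20]
        rates = occupied["observed_rate"].to_numpy()
        assert (np.diff(rates) > -0.05).all()  # non-decreasing up to noise


class TestEvaluateScores:
    def test_report_structure(self, small_cohort):
        cohort, truth = small_cohort
        report = ps.evaluate_scores(truth.true_totals, cohort.y, reps=150, seed=0)
        assert 0.5 < report.auc <= 1.0
        assert report.auc_ci[0] <= report.auc <= report.auc_ci[1]
        assert report.calibration["n"].sum() == cohort.n
        labels = [m.label for m in report.thresholds]
        assert "optimal" in labels
        md = report.to_markdown()
        assert "AUC" in md and "threshold" in md.lower()
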