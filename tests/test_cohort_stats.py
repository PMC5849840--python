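import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from olvpredict.cohort_stats import (
    ParotidRecord,
    backward_stepwise_aic,
    fit_linear,
    frame_to_records,
    optimal_operating_point,
    records_to_frame,
    roc_curve,
)


def make_record(**over):
    base = dict(plan_id="p", side="L", volume_cc=30.0,
                olv_ct=0.2, olv_ct05=0.3, olv_ct10=0.4,
                olv_hd=0.05, olv_hd05=0.1, olv_im=0.1, olv_ld=0.2, d_mean=20.0)
    base.update(over)
    return ParotidRecord(**base)


class TestParotidRecord:
    def test_positive_label_is_strictly_above_26(self):
        assert not make_record(d_mean=26.0).positive
        assert make_record(d_mean=26.01).positive

    def test_expansion_monotonicity_enforced(self):
        with pytest.raises(ValueError, match="monotonicity"):
            make_record(olv_ct=0.5, olv_ct05=0.3)
        with pytest.raises(ValueError, match="monotonicity"):
            make_record(olv_hd=0.3, olv_hd05=0.1)

    def test_olv_bounds_enforced(self):
        with pytest.raises(ValueError):
            make_record(olv_ld=1.2)

    def test_frame_round_trip(self):
        recs = [make_record(), make_record(side="R", d_mean=None)]
        back = frame_to_records(records_to_frame(recs))
        assert back[0].d_mean == 20.0
        assert back[1].d_mean is None
        assert back[1].olv_hd05 == 0.1


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_linear(2 * x + 1, x[:, None], names=["x"])
        assert fit.coefficients == pytest.approx([1.0, 2.0], abs=1e-10)
        assert fit.r_squared == 1.0

    def test_constant_outcome_has_zero_r2(self):
        rng = np.random.default_rng(0)
        fit = fit_linear(np.full(20, 3.0), rng.random((20, 2)))
        assert fit.r_squared == 0.0

    def test_five_point_fit_matches_normal_equations_oracle(self):
        x = np.array([0.1, 0.4, 0.5, 0.9, 1.3])
        y = np.array([10.0, 14.0, 13.0, 22.0, 24.0])
        design = np.column_stack([np.ones(5), x])
        beta_oracle = np.linalg.solve(design.T @ design, design.T @ y)
        fit = fit_linear(y, x[:, None])
        np.testing.assert_allclose(fit.coefficients, beta_oracle, atol=1e-10)

    def test_against_statsmodels_conventions(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        X = rng.random((40, 3))
        y = 3 + X @ np.array([2.0, -1.0, 0.3]) + rng.standard_normal(40)
        fit = fit_linear(y, X)
        res = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.coefficients, res.params, atol=1e-9)
        assert fit.r_squared == pytest.approx(res.rsquared, abs=1e-10)
        np.testing.assert_allclose(fit.slope_pvalues, res.pvalues[1:], atol=1e-10)
        # statsmodels does not count sigma as a parameter; this AIC does
        assert fit.aic == pytest.approx(res.aic + 2.0, abs=1e-8)

    def test_univariate_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(7)
        x = rng.random(60)
        y = 1.5 * x + rng.standard_normal(60) * 0.3
        fit = fit_linear(y, x[:, None])
        assert fit.r_squared == pytest.approx(stats.pearsonr(x, y)[0] ** 2, abs=1e-10)
        assert fit.p_value == pytest.approx(stats.pearsonr(x, y)[1], abs=1e-10)

    def test_rank_deficiency_names_dependent_column(self):
        rng = np.random.default_rng(2)
        x1 = rng.random(30)
        X = pd.DataFrame({"a": x1, "b": 2 * x1, "c": rng.random(30)})
        with pytest.raises(ValueError, match="b"):
            fit_linear(rng.random(30), X)

    def test_too_few_observations_raises(self):
        with pytest.raises(ValueError, match="n >= p"):
            fit_linear(np.ones(3), np.ones((3, 2)))

    def test_slope_ci_coverage(self):
        """95% t-interval on the slope covers the truth ~95% of the time."""
        rng = np.random.default_rng(123)
        n, hits, reps = 30, 0, 1000
        for _ in range(reps):
            x = rng.random(n)
            y = 1.0 + 2.0 * x + rng.standard_normal(n)
            fit = fit_linear(y, x[:, None])
            half = stats.t.ppf(0.975, n - 2) * fit.slope_standard_errors[0]
            slope = fit.coefficients[1]
            hits += (slope - half) <= 2.0 <= (slope + half)
        assert hits / reps == pytest.approx(0.95, abs=0.03)


def exhaustive_best_subset(y, X: pd.DataFrame):
    best = None
    for k in range(len(X.columns) + 1):
        for combo in itertools.combinations(X.columns, k):
            fit = fit_linear(y, X[list(combo)])
            if best is None or fit.aic < best[1]:
                best = (set(combo), fit.aic)
    return best[0]


class TestStepwise:
    def test_single_driver_survives(self):
        rng = np.random.default_rng(1)
        n = 100
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=["x1", "x2", "x3"])
        y = 5.0 * X["x1"].to_numpy() + rng.standard_normal(n)
        selected, fit = backward_stepwise_aic(y, X)
        assert selected == ["x1"]
        assert exhaustive_best_subset(y, X) == {"x1"}

    def test_pure_noise_collapses_to_intercept(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((100, 3)), columns=["x1", "x2", "x3"])
        y = rng.standard_normal(100)
        selected, fit = backward_stepwise_aic(y, X)
        assert selected == []
        assert exhaustive_best_subset(y, X) == set()

    def test_correlated_predictors_collapse_to_strongest(self):
        # mirrors collinear overlap fractions: one drives the outcome
        rng = np.random.default_rng(8)
        n = 120
        base = rng.standard_normal(n)
        X = pd.DataFrame({
            "x1": base + 0.1 * rng.standard_normal(n),
            "x2": base + 0.8 * rng.standard_normal(n),
            "x3": base + 0.8 * rng.standard_normal(n),
        })
        y = 4.0 * X["x1"].to_numpy() + rng.standard_normal(n)
        selected, _ = backward_stepwise_aic(y, X)
        assert selected == ["x1"]
        assert exhaustive_best_subset(y, X) == {"x1"}

    def test_final_model_is_locally_aic_optimal(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = 60
            X = pd.DataFrame(rng.standard_normal((n, 4)),
                             columns=["x1", "x2", "x3", "x4"])
            beta = rng.standard_normal(4) * rng.integers(0, 2, 4)
            y = X.to_numpy() @ beta + rng.standard_normal(n)
            selected, fit = backward_stepwise_aic(y, X)
            full = fit_linear(y, X)
            assert fit.aic <= full.aic
            for name in selected:
                kept = [c for c in selected if c != name]
                sub = fit_linear(y, X[kept]) if kept else fit_linear(
                    y, np.empty((n, 0)))
                assert sub.aic >= fit.aic


def auc_pair_oracle(scores, labels):
    """Mann-Whitney pair counting with ties worth half."""
    s = np.asarray(scores, float)
    lab = np.asarray(labels, bool)
    pos, neg = s[lab], s[~lab]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestRocProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        scores=st.lists(st.floats(0, 1, allow_nan=False, width=32),
                        min_size=2, max_size=40),
        labels=st.data(),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_auc_always_equals_pair_statistic(self, scores, labels):
        lab = labels.draw(self.st.lists(self.st.booleans(),
                                        min_size=len(scores),
                                        max_size=len(scores)))
        if all(lab) or not any(lab):
            return
        rc = roc_curve(scores, lab)
        assert rc.auc == pytest.approx(auc_pair_oracle(scores, lab), abs=1e-12)
        # endpoints of the sweep are fixed by construction
        assert (rc.sensitivity[0], rc.specificity[0]) == (1.0, 0.0)
        assert (rc.sensitivity[-1], rc.specificity[-1]) == (0.0, 1.0)
        op = optimal_operating_point(rc)
        assert -1.0 <= op.youden_j <= 1.0


class TestRoc:
    def test_perfect_separation(self):
        rc = roc_curve([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert rc.auc == 1.0
        op = optimal_operating_point(rc)
        assert op.youden_j == 1.0
        assert op.threshold == pytest.approx(0.5)

    def test_all_tied_scores_give_chance_auc(self):
        rc = roc_curve([0.3, 0.3, 0.3, 0.3], [False, True, False, True])
        assert rc.auc == pytest.approx(0.5, abs=1e-12)

    def test_worked_example_auc_075(self):
        rc = roc_curve([0.1, 0.4, 0.35, 0.8], [False, False, True, True])
        assert rc.auc == pytest.approx(0.75, abs=1e-12)
        op = optimal_operating_point(rc)
        assert op.threshold == pytest.approx(0.225)
        assert op.sensitivity == 1.0
        assert op.specificity == 0.5

    def test_curve_endpoints(self):
        rc = roc_curve([0.2, 0.6, 0.4], [True, False, True])
        assert (rc.sensitivity[0], rc.specificity[0]) == (1.0, 0.0)
        assert (rc.sensitivity[-1], rc.specificity[-1]) == (0.0, 1.0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([0.1, 0.2], [True, True])

    def test_matches_pair_counting_and_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(4, 50))
            scores = rng.choice([0.0, 0.1, 0.25, 0.5, 0.7, 1.0], n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            rc = roc_curve(scores, labels)
            assert rc.auc == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)
            assert rc.auc == pytest.approx(
                sk.roc_auc_score(labels, scores), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.random(40)
        labels = rng.random(40) < 0.4
        if labels.all() or not labels.any():
            labels[:2] = [True, False]
        base = roc_curve(scores, labels).auc
        for f in (lambda s: 3 * s + 2, np.exp, lambda s: s**3):
            assert roc_curve(f(scores), labels).auc == pytest.approx(base, abs=1e-12)

    def test_shifting_scores_shifts_threshold(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = [False, False, True, True]
        op = optimal_operating_point(roc_curve(scores, labels))
        op2 = optimal_operating_point(roc_curve(scores + 1.7, labels))
        assert op2.threshold == pytest.approx(op.threshold + 1.7)
        assert (op2.sensitivity, op2.specificity) == (op.sensitivity, op.specificity)
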