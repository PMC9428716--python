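import warnings

import numpy as np
import pytest

from tsdfc.model import (
    ConnectivityClassifier,
    compute_metrics,
    fit_outer_fold,
    lasso_select,
    majority_vote,
    nested_loocv,
    pooled_ttest_from_summary,
    report_feature_weights,
    train_predict_svm,
)

from oracles import soft_threshold_oracle


class TestLassoSelect:
    def _orthonormal_design(self, s, m, seed):
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.standard_normal((s, m)))
        return q[:, :m]

    def test_penalty_above_lambda_max_selects_nothing(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 5))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.choice([-1.0, 1.0], size=20)
        lam_max = np.max(np.abs(X.T @ (y - y.mean())))
        selected, coef, _ = lasso_select(X, y, lam_max * 1.001)
        assert selected.size == 0 and np.all(coef == 0)

    def test_zero_penalty_is_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        selected, coef, intercept = lasso_select(X, y, 0.0)
        design = np.hstack([X, np.ones((30, 1))])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        assert np.allclose(coef, beta[:-1], atol=1e-10)
        assert intercept == pytest.approx(beta[-1], abs=1e-10)
        assert selected.size == 4

    def test_orthonormal_design_soft_threshold_closed_form(self):
        rng = np.random.default_rng(2)
        for lam in (0.05, 0.2, 0.5):
            X = self._orthonormal_design(40, 6, seed=int(lam * 100))
            X = X - X.mean(axis=0)  # keep columns centered for the intercept
            # re-orthonormalize after centering
            q, _ = np.linalg.qr(X)
            X = q
            beta_true = rng.standard_normal(6)
            y = X @ beta_true
            beta_ols = X.T @ y
            _, coef, _ = lasso_select(X, y, lam)
            want = soft_threshold_oracle(beta_ols, lam)
            assert np.max(np.abs(coef - want)) <= 1e-8


class TestSvm:
    def test_separable_training_is_perfect(self):
        X = np.array([[0.0, 0], [0, 1], [5, 5], [5, 6]])
        y = np.array([-1, -1, 1, 1])
        for i in range(4):
            label, _ = train_predict_svm(X, y, X[i])
            assert label == y[i]

    def test_deep_point_classified_positive(self):
        X = np.array([[0.0, 0], [0, 1], [5, 5], [5, 6]])
        y = np.array([-1, -1, 1, 1])
        label, score = train_predict_svm(X, y, np.array([50.0, 50.0]))
        assert label == 1 and score > 1

    def test_mirror_symmetry_negates_score(self):
        rng = np.random.default_rng(3)
        Xp = rng.normal(1.5, 0.5, size=(10, 3))
        X = np.vstack([Xp, -Xp])
        y = np.array([1] * 10 + [-1] * 10)
        point = np.array([0.7, -0.2, 0.4])
        _, s1 = train_predict_svm(X, y, point)
        _, s2 = train_predict_svm(X, y, -point)
        assert s2 == pytest.approx(-s1, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_predict_svm(np.zeros((3, 2)), np.array([1, 1, 1]), np.zeros(2))


class TestMajorityVote:
    def test_simple_majority(self):
        assert majority_vote([1, 1, -1], [0.5, 0.2, -0.1]) == 1

    def test_tie_broken_by_mean_score(self):
        votes = [1] * 60 + [-1] * 60
        scores = [0.1] * 60 + [-0.5] * 60  # mean -0.2
        assert majority_vote(votes, scores) == -1

    def test_single_vote(self):
        assert majority_vote([-1], [-0.3]) == -1

    def test_zero_mean_tie_resolves_positive(self):
        with pytest.warns(RuntimeWarning, match="tie"):
            assert majority_vote([1, -1], [0.2, -0.2]) == 1


class TestMetrics:
    def test_implied_confusion_matrix_from_class_rates(self):
        # 57 positives with 47 hits, 64 negatives with 52 hits
        y_true = np.array([1] * 57 + [-1] * 64)
        y_pred = np.array([1] * 47 + [-1] * 10 + [-1] * 52 + [1] * 12)
        m = compute_metrics(y_true, y_pred)
        assert m.ACC * 100 == pytest.approx(81.82, abs=0.005)
        assert m.SEN * 100 == pytest.approx(82.46, abs=0.005)
        assert m.SPE * 100 == pytest.approx(81.25, abs=0.005)
        assert m.TP + m.TN + m.FP + m.FN == 121

    def test_perfect_predictions(self):
        y = np.array([1, 1, -1, -1])
        scores = np.array([2.0, 1.0, -1.0, -2.0])
        m = compute_metrics(y, y, scores)
        assert m.ACC == m.SEN == m.SPE == m.AUC == 1.0

    def test_constant_scores_give_half_auc(self):
        y = np.array([1, -1, 1, -1])
        m = compute_metrics(y, y, np.zeros(4))
        assert m.AUC == pytest.approx(0.5)

    def test_acc_is_count_ratio(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            y = rng.choice([-1, 1], size=15)
            p = rng.choice([-1, 1], size=15)
            if len(set(y)) < 2:
                continue
            m = compute_metrics(y, p)
            assert m.ACC == (m.TP + m.TN) / 15

    def test_no_positives_warns_nan_sensitivity(self):
        with pytest.warns(RuntimeWarning, match="sensitivity"):
            m = compute_metrics([-1, -1], [-1, 1])
        assert np.isnan(m.SEN)


class TestPooledTTest:
    def test_cohort_demographics_value(self):
        p = pooled_ttest_from_summary(36.684, 13.620, 57, 35.313, 11.804, 64)
        assert round(p, 3) == 0.554

    def test_identical_summaries_give_p_one(self):
        assert pooled_ttest_from_summary(5, 2, 10, 5, 2, 10) == pytest.approx(1.0)

    def test_closed_form_case(self):
        # t = -2 / sqrt(1 * (1/10 + 1/10)) = -4.4721, df = 18
        from scipy import stats

        p = pooled_ttest_from_summary(1, 1, 10, 3, 1, 10)
        want = 2 * stats.t.sf(2.0 / np.sqrt(0.2), df=18)
        assert p == pytest.approx(want, rel=1e-9)
        assert p == pytest.approx(2.9e-4, rel=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pooled_ttest_from_summary(1, 1, 1, 2, 1, 10)
        with pytest.raises(ValueError):
            pooled_ttest_from_summary(1, 0, 10, 2, 1, 10)


GRIDS = dict(
    window_lengths=[10],
    cluster_counts=[5],
    retain_fractions=[0.5],
    lasso_penalties=[0.3],
)


class TestNestedLoocv:
    def test_one_prediction_per_subject_and_summary(self, tiny_cohort):
        series, manifest = tiny_cohort
        model = ConnectivityClassifier(series, manifest.labels, **GRIDS)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(seed=0)
        assert len(res.cv.y_pred) == len(series)
        assert set(res.cv.y_pred.tolist()) <= {-1, 1}
        # each fold's ensemble has S-1 voters
        assert all(v[0] + v[1] == len(series) - 1 for v in res.cv.vote_tally)
        text = res.summary()
        assert "ACC" in text and "nested LOOCV" in text

    def test_separable_cohort_classified_well(self, tiny_cohort):
        series, manifest = tiny_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = nested_loocv(series, manifest.labels, seed=0, **GRIDS)
        assert cv.metrics.ACC >= 0.75

    def test_feature_weights_normalized(self, tiny_cohort):
        series, manifest = tiny_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = nested_loocv(series, manifest.labels, seed=0, **GRIDS)
        df = report_feature_weights(cv)
        assert len(df) > 0
        assert df["weight"].max() == pytest.approx(1.0)
        assert (df["weight"] >= 0).all()
        assert set(df["kind"]) <= {"variability", "strength", "clustering"}

    def test_too_few_subjects_rejected(self, tiny_cohort):
        series, manifest = tiny_cohort
        with pytest.raises(ValueError, match="at least 4"):
            nested_loocv(series[:3], manifest.labels[:3], **GRIDS)

    def test_single_class_labels_rejected(self, tiny_cohort):
        series, _ = tiny_cohort
        with pytest.raises(ValueError, match="both"):
            nested_loocv(series, np.ones(len(series), dtype=int), **GRIDS)


class TestLeakageAudit:
    def test_corrupting_held_out_subject_changes_nothing_fitted(self, tiny_cohort):
        """In leakage-free mode no fitted parameter of an outer fold may
        depend on the held-out subject's data."""
        series, manifest = tiny_cohort
        test_idx = 2

        def run(subjects):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return fit_outer_fold(
                    subjects, manifest.labels, test_idx, seed=0, **GRIDS
                )

        clean = run(series)
        rng = np.random.default_rng(123)
        corrupted = list(series)
        ts = corrupted[test_idx]
        from tsdfc.io import RoiTimeSeries

        corrupted[test_idx] = RoiTimeSeries(
            ts.subject_id,
            rng.standard_normal(ts.data.shape) * 37.0 + 5.0,
            ts.roi_names,
        )
        dirty = run(corrupted)

        assert clean["combo"] == dirty["combo"]
        assert clean["inner_accuracy"] == dirty["inner_accuracy"]
        for a, b in zip(clean["members"], dirty["members"]):
            assert np.array_equal(a.assignment, b.assignment)
            assert np.array_equal(a.mean, b.mean)
            assert np.array_equal(a.sd, b.sd)
            assert np.array_equal(a.selected, b.selected)
            assert np.array_equal(a.lasso_coef, b.lasso_coef)
            assert np.array_equal(a.svm.coef_, b.svm.coef_)
            assert np.array_equal(a.svm.intercept_, b.svm.intercept_)
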