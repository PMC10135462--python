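import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from cerna_forge.io_prep import make_sample_table
from cerna_forge.signature import (
    _cd_logistic,
    auc_score,
    cross_validate,
    evaluate_roc,
    lasso_path_logistic,
    lasso_select,
    penalized_objective,
    predict_scores,
    rf_fit_and_importance,
    roc_curve_points,
    split_train_validation,
)


def _cohort(rng, n_per_group, n_features, informative=0, effect=1.5):
    t = make_sample_table(
        [f"s{i}" for i in range(2 * n_per_group)],
        ["control"] * n_per_group + ["case"] * n_per_group,
    )
    x = pd.DataFrame(
        rng.normal(size=(n_features, 2 * n_per_group)),
        index=[f"G{i}" for i in range(n_features)],
        columns=t["sample_id"],
    )
    for i in range(informative):
        x.iloc[i, n_per_group:] += effect
    return x, t


class TestSplit:
    def test_stratified_sizes(self, two_group_table):
        t = two_group_table(10, 10)
        train, valid = split_train_validation(t, 0.8, seed=5)
        assert len(train) == 16 and len(valid) == 4
        assert (train["group"] == "case").sum() == 8
        assert (valid["group"] == "case").sum() == 2

    def test_full_fraction_empty_validation_warns(self, two_group_table):
        t = two_group_table(5, 5)
        with pytest.warns(UserWarning, match="empty"):
            train, valid = split_train_validation(t, 1.0, seed=1)
        assert len(valid) == 0

    def test_deterministic_given_seed(self, two_group_table):
        t = two_group_table(8, 8)
        a = split_train_validation(t, 0.75, seed=3)
        b = split_train_validation(t, 0.75, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_tiny_group_rejected(self, two_group_table):
        t = two_group_table(1, 5)
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_validation(t, 0.8, seed=0)


class TestLassoSolver:
    def test_huge_lambda_gives_empty_model(self, rng):
        x, t = _cohort(rng, 10, 8, informative=3)
        X = x.to_numpy().T
        Xs = (X - X.mean(0)) / X.std(0)
        y = np.array([0.0] * 10 + [1.0] * 10)
        _, _, betas = lasso_path_logistic(Xs, y, lambdas=[10.0])
        assert (betas[0] == 0).all()

    def test_perfect_separator_selected(self, rng):
        x, t = _cohort(rng, 12, 10)
        x.loc["G0"] = [0.0] * 12 + [1.0] * 12  # equals the group label
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = lasso_select(x, t, n_folds=5, seed=1)
        assert "G0" in {g for g, _ in sel}

    def test_zero_lambda_matches_unpenalized_logistic(self, rng):
        x, t = _cohort(rng, 40, 3, informative=1, effect=1.0)
        X = x.to_numpy().T
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        y = np.array([0.0] * 40 + [1.0] * 40)
        _, b0s, betas = lasso_path_logistic(Xs, y, lambdas=[1e-3, 1e-10])
        ref = LogisticRegression(C=np.inf, tol=1e-10, max_iter=5000).fit(Xs, y)
        assert betas[-1] == pytest.approx(ref.coef_[0], abs=1e-4)
        assert b0s[-1] == pytest.approx(ref.intercept_[0], abs=1e-4)

    def test_kkt_conditions_at_convergence(self, rng):
        x, t = _cohort(rng, 25, 10, informative=3)
        X = x.to_numpy().T
        Xs = (X - X.mean(0)) / X.std(0)
        y = np.array([0.0] * 25 + [1.0] * 25)
        lam = 0.05
        beta0, beta = _cd_logistic(Xs, y, lam, 0.0, np.zeros(10), tol=1e-12)
        n = len(y)
        mu = 1.0 / (1.0 + np.exp(-(beta0 + Xs @ beta)))
        grad = Xs.T @ (y - mu) / n
        for j in range(10):
            if beta[j] == 0:
                assert abs(grad[j]) <= lam + 1e-6
            else:
                assert grad[j] - lam * np.sign(beta[j]) == pytest.approx(0.0, abs=1e-6)

    def test_objective_non_increasing_over_irls_steps(self, rng):
        x, t = _cohort(rng, 20, 6, informative=2)
        X = x.to_numpy().T
        Xs = (X - X.mean(0)) / X.std(0)
        y = np.array([0.0] * 20 + [1.0] * 20)
        trace: list = []
        _cd_logistic(Xs, y, 0.02, 0.0, np.zeros(6), trace=trace)
        assert len(trace) >= 1
        diffs = np.diff(trace)
        assert (diffs <= 1e-8).all()

    def test_selection_consistency_on_planted_signal(self, rng):
        recovered = []
        for seed in range(10):
            local = np.random.default_rng(seed)
            x, t = _cohort(local, 22, 30, informative=5, effect=1.5)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = lasso_select(x, t, n_folds=10, seed=seed)
            kept = {g for g, _ in sel}
            recovered.append(len(kept & {f"G{i}" for i in range(5)}))
        assert np.mean([r >= 4 for r in recovered]) >= 0.8


class TestRandomForest:
    def test_perfect_feature_dominates_importance(self, rng):
        x, t = _cohort(rng, 15, 5)
        x.loc["G0"] = [0.0] * 15 + [1.0] * 15
        model = rf_fit_and_importance(x, t, n_trees=100, seed=2)
        imp = model.importance
        assert imp["%IncMSE"].idxmax() == "G0"
        assert imp["IncNodePurity"].idxmax() == "G0"

    def test_noise_features_have_near_zero_permutation_importance(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x, t = _cohort(rng, 12, 4)
            model = rf_fit_and_importance(x, t, n_trees=60, seed=seed)
            vals.append(model.importance["%IncMSE"].to_numpy())
        vals = np.array(vals)
        mean = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(mean) <= 2 * se + 1.0

    def test_deterministic_given_seed(self, rng):
        x, t = _cohort(rng, 10, 6, informative=2)
        a = rf_fit_and_importance(x, t, n_trees=50, seed=7)
        b = rf_fit_and_importance(x, t, n_trees=50, seed=7)
        pd.testing.assert_frame_equal(a.importance, b.importance)

    def test_single_class_rejected(self, rng):
        x, t = _cohort(rng, 5, 4)
        t["group"] = "case"
        with pytest.raises(ValueError, match="single class"):
            rf_fit_and_importance(x, t, n_trees=10, seed=0)

    def test_missing_feature_in_external_cohort_raises(self, rng):
        x, t = _cohort(rng, 8, 4)
        model = rf_fit_and_importance(x, t, n_trees=20, seed=0)
        with pytest.raises(ValueError, match="G0"):
            predict_scores(model, x.drop(index="G0"))


class TestAUC:
    def test_perfect_ordering(self):
        assert auc_score([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_score([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_one_swap_gives_three_quarters(self):
        assert auc_score([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 20))
            scores = rng.integers(0, 6, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            brute = np.mean(
                [[1.0 if p > q else (0.5 if p == q else 0.0) for q in neg] for p in pos]
            )
            assert auc_score(scores, labels) == pytest.approx(brute, abs=1e-12)
            assert auc_score(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_roc_curve_monotone(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        _, sens, spec = roc_curve_points(scores, labels)
        assert (np.diff(sens) >= 0).all()
        assert (np.diff(spec) <= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([0.1, 0.2], [1, 1])


class TestEvaluateAndCrossValidate:
    def test_informative_signature_separates_groups(self, rng):
        x, t = _cohort(rng, 15, 6, informative=4, effect=2.0)
        model = rf_fit_and_importance(x, t, n_trees=100, seed=3)
        roc = evaluate_roc(model, x, t)
        assert roc.auc > 0.9

    def test_loocv_mechanics(self, rng):
        x, t = _cohort(rng, 5, 4, informative=2, effect=2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean_auc, folds = cross_validate(x, t, n_folds=5, seed=1, n_trees=25)
        assert len(folds) == 5
        assert 0.0 <= mean_auc <= 1.0

    def test_fold_without_both_classes_advises(self, rng):
        x, t = _cohort(rng, 3, 4)
        with pytest.raises(ValueError, match="fewer folds"):
            cross_validate(x, t, n_folds=5, seed=0, n_trees=10)
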