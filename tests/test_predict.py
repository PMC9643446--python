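"""mRMR, the model pipelines, metrics and the two-layer CV engine."""

import json
from itertools import product

import numpy as np
import pytest
from scipy import stats as sstats

from eegmark.predict import (
    ModelGrid,
    balanced_accuracy,
    baseline_test,
    fit_pipeline,
    mrmr_select,
    nmae,
    run_two_layer_cv,
)

TINY_GRID = ModelGrid(
    mrmr_k=(3,),
    logistic_C=np.array([1.0]),
    svm_C=np.array([0.1]),
    rf_trees=(10,),
    rf_depth=(1,),
    regression_alpha=np.array([1.0]),
)


def _mrmr_oracle(X, y, k):
    """Step-by-step exhaustive maximization of the greedy mRMR objective."""
    from sklearn.feature_selection import f_classif

    F, _ = f_classif(X, y)
    Z = (X - X.mean(0)) / X.std(0)
    n = len(y)
    selected = [int(np.argmax(F))]
    while len(selected) < k:
        best, best_score = None, -np.inf
        for j in range(X.shape[1]):
            if j in selected:
                continue
            red = np.mean([abs(Z[:, j] @ Z[:, s]) / n for s in selected])
            score = F[j] / max(red, 1e-12)
            if score > best_score:
                best, best_score = j, score
        selected.append(best)
    return selected


class TestMrmr:
    def test_k1_picks_max_relevance_per_type(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 20)
        X = rng.standard_normal((40, 6))
        X[:, 2] += 2.0 * y  # strongest in type a
        X[:, 5] += 1.5 * y  # strongest in type b
        types = np.array(["a"] * 3 + ["b"] * 3)
        sel = mrmr_select(X, y, 1, types)
        assert set(sel) == {2, 5}

    def test_duplicate_of_top_feature_never_chosen_second(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 20)
        X = rng.standard_normal((40, 5))
        X[:, 0] += 2.0 * y
        X[:, 1] = X[:, 0]  # exact duplicate
        sel = mrmr_select(X, y, 2, None, mode="global")
        assert 0 in sel and 1 not in sel

    def test_greedy_path_matches_exhaustive_objective(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 15)
        X = rng.standard_normal((30, 6))
        X[:, 0] += 1.0 * y
        X[:, 3] += 0.5 * y
        sel = mrmr_select(X, y, 5, None, mode="global")
        assert sorted(sel) == sorted(_mrmr_oracle(X, y, 5))

    def test_zero_variance_feature_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 10)
        X = rng.standard_normal((20, 4))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            sel = mrmr_select(X, y, 4, None, mode="global")
        assert 1 not in sel


class TestMetrics:
    def test_balanced_accuracy_cases(self):
        assert balanced_accuracy([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0
        assert balanced_accuracy([0, 0, 0, 1], [0, 0, 0, 0]) == 0.5
        # printed 4-sample case: sens 0.5, spec 1.0
        assert balanced_accuracy([1, 1, 0, 0], [1, 0, 0, 0]) == 0.75
        with pytest.raises(ValueError):
            balanced_accuracy([1, 1], [1, 0])

    def test_nmae_cases(self):
        y = np.array([0.0, 2.0])
        assert nmae(y, np.array([0.0, 0.0]), train_mean=1.0) == 1.0
        assert nmae(y, y, train_mean=1.0) == 0.0
        assert nmae(y, np.full(2, y.mean()), train_mean=float(y.mean())) == 1.0
        with pytest.raises(ValueError):
            nmae([1.0, 1.0], [1.0, 1.0], train_mean=1.0)


class TestBaselineTest:
    def test_all_at_baseline_gives_p_one(self):
        assert baseline_test(np.full(100, 0.5), 0.5) == 1.0

    def test_uniform_improvement_is_significant(self):
        assert baseline_test(np.full(100, 0.6), 0.5) < 0.01

    def test_small_sample_matches_sign_pattern_enumeration(self):
        diffs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -1.0])
        ranks = sstats.rankdata(np.abs(diffs))
        obs = ranks[diffs > 0].sum()
        dist = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in product([0, 1], repeat=6)
        ]
        p_oracle = np.mean([d >= obs for d in dist])
        assert baseline_test(diffs + 0.5, 0.5) == pytest.approx(p_oracle)


class TestPipelines:
    def _xy(self, seed=0, n=40, p=12):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, p))
        X[y == 1, :2] += 1.5
        return X, y

    def test_rfe_reduces_pool_to_target_count(self):
        X, y = self._xy()
        fp = fit_pipeline(X, y, "svm", {"C": 0.1}, 4, None, "classification")
        assert len(fp.features) == 4

    def test_forward_selection_has_no_duplicates(self):
        X, y = self._xy(1)
        fp = fit_pipeline(X, y, "logl2", {"C": 1.0}, 6, None, "classification")
        assert len(fp.features) == len(set(fp.features))

    def test_fully_shrunk_lasso_predicts_majority_class(self):
        X, y = self._xy(2)
        y = np.array([0] * 25 + [1] * 15)
        fp = fit_pipeline(X, y, "logl1", {"C": 1e-6}, 5, None, "classification")
        assert fp.majority == 0.0
        assert np.all(fp.predict(X) == 0)


class TestTwoLayerCv:
    def test_bookkeeping_100_outer_models_without_leak(self, toy_xy):
        X, y, types = toy_xy
        report = run_two_layer_cv(
            X, y, types, models=("logl1",), grid=TINY_GRID,
            repeats=10, outer_k=10, inner_k=10, seed=0,
        )
        assert len(report.folds) == 100
        for _, row in report.folds.iterrows():
            test = set(json.loads(row["test_subjects"]))
            train = set(json.loads(row["train_subjects"]))
            assert not test & train
            assert len(test | train) == len(y)
            # stratification: class balance within one subject of global
            te = sorted(test)
            assert abs(np.mean(y[te]) - 0.5) <= 1.0 / len(te)

    def test_fixed_seed_reproduces_report(self, toy_xy):
        X, y, types = toy_xy
        kw = dict(models=("logl1",), grid=TINY_GRID, repeats=2, outer_k=5,
                  inner_k=3, seed=3)
        a = run_two_layer_cv(X, y, types, **kw)
        b = run_two_layer_cv(X, y, types, **kw)
        assert a.folds.equals(b.folds)

    def test_separable_clusters_reach_high_test_accuracy(self):
        rng = np.random.default_rng(4)
        n = 40
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 10))
        X[y == 1, :4] += 4.0
        report = run_two_layer_cv(
            X, y, None, models=("logl1",), grid=TINY_GRID,
            repeats=2, outer_k=5, inner_k=3, seed=5,
        )
        assert report.folds["test_score"].mean() >= 0.95

    def test_perturbing_a_test_subject_never_changes_the_fitted_model(self, toy_xy):
        """Leakage instrumentation: the pipeline fitted for a fold must not
        depend on that fold's test data."""
        X, y, types = toy_xy
        kw = dict(models=("logl1",), grid=TINY_GRID, repeats=1, outer_k=5,
                  inner_k=3, seed=6)
        base = run_two_layer_cv(X, y, types, **kw)
        X2 = X.copy()
        X2[0] += 100.0
        pert = run_two_layer_cv(X2, y, types, **kw)
        for (_, ra), (_, rb) in zip(base.folds.iterrows(), pert.folds.iterrows()):
            if 0 in json.loads(ra["test_subjects"]):
                assert ra["selected"] == rb["selected"]
                assert ra["params"] == rb["params"]
                assert ra["mrmr_k"] == rb["mrmr_k"]

    def test_too_few_subjects_per_class_rejected(self):
        X = np.zeros((8, 3))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(ValueError):
            run_two_layer_cv(X, y, None, grid=TINY_GRID, outer_k=10)

    def test_regression_reports_nmae_scale(self):
        rng = np.random.default_rng(7)
        n = 40
        strat = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 8))
        y = 2.0 * X[:, 0] + 0.3 * rng.standard_normal(n)
        report = run_two_layer_cv(
            X, y, None, models=("ridge_reg",), grid=TINY_GRID, repeats=2,
            outer_k=5, inner_k=3, seed=8, task="regression", stratify=strat,
        )
        # scores are -nMAE: a strongly predictable target beats the mean
        assert report.folds["test_score"].mean() > -1.0
        summary = report.summary()
        assert summary.loc["ridge_reg", "baseline_p"] < 0.2
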