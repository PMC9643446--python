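"""Multivariate prediction: mRMR feature selection, four classifier and two
regressor pipelines, and repeated stratified two-layer cross-validation.

Every pipeline is [z-score standardization -> per-type mRMR pool ->
model-specific selection -> estimator], with all statistics (scaling means,
selection, hyperparameters) fit strictly inside the training partition of the
fold at hand: the outer folds estimate generalization on unseen subjects, the
inner folds tune hyperparameters.  Classifier skill is balanced accuracy
(chance = 0.5 for two classes regardless of imbalance); regressor skill is
nMAE, the MAE of the model divided by the MAE of predicting the training-set
mean (1 = no better than the mean).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.feature_selection import RFE, f_classif, f_regression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Lasso, LogisticRegression, Ridge
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

CLASSIFIERS = ("svm", "logl2", "logl1", "rf")
REGRESSORS = ("lasso_reg", "ridge_reg")


@dataclass
class ModelGrid:
    """Hyperparameter grids (log-spaced grids include both endpoints)."""

    mrmr_k: tuple = (10, 20, 30, 40)
    logistic_C: np.ndarray = field(
        default_factory=lambda: np.logspace(np.log10(0.01), np.log10(1000), 16)
    )
    svm_C: np.ndarray = field(
        default_factory=lambda: np.logspace(np.log10(0.001), np.log10(1), 13)
    )
    rf_trees: tuple = (10, 50, 100, 500, 1000)
    rf_depth: tuple = (1, 2)
    regression_alpha: np.ndarray = field(
        default_factory=lambda: 1.0 / np.logspace(np.log10(0.01), np.log10(1000), 16)
    )
    forward_cap: int = 20

    @classmethod
    def reduced(cls) -> "ModelGrid":
        """Desk-scale grid for small cohorts and quick runs."""
        return cls(
            mrmr_k=(10, 20),
            logistic_C=np.logspace(-2, 2, 4),
            svm_C=np.logspace(-3, 0, 4),
            rf_trees=(10, 100),
            rf_depth=(1, 2),
            regression_alpha=1.0 / np.logspace(-2, 2, 4),
            forward_cap=10,
        )


# ---------------------------------------------------------------------------
# metrics


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """(sensitivity + specificity) / 2."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("balanced accuracy undefined for single-class y_true")
    return float(balanced_accuracy_score(y_true, y_pred))


def nmae(y_true: np.ndarray, y_pred: np.ndarray, train_mean: float) -> float:
    """MAE(y, y_hat) / MAE(y, train-mean constant)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty vectors")
    denom = np.abs(y_true - train_mean).mean()
    if denom == 0:
        raise ValueError("nMAE undefined: y_true constant at the train mean")
    return float(np.abs(y_true - y_pred).mean() / denom)


def baseline_test(scores: np.ndarray, baseline: float, side: str = "greater") -> float:
    """One-sided Wilcoxon signed-rank of scores against a fixed baseline.

    ``side='greater'`` for accuracies vs 0.5, ``side='less'`` for nMAE vs 1.
    All-zero differences give p = 1 by convention.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 6:
        raise ValueError("need >= 6 paired scores")
    diffs = scores - baseline
    if np.all(diffs == 0):
        return 1.0
    res = sstats.wilcoxon(diffs, alternative=side)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# mRMR


def _relevance(X: np.ndarray, y: np.ndarray, task: str) -> np.ndarray:
    f = f_classif if task == "classification" else f_regression
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f(X, y)
    return np.nan_to_num(F, nan=0.0, posinf=0.0)


def _greedy_mrmr(Xs: np.ndarray, F: np.ndarray, k: int) -> list[int]:
    """Greedy quotient-scheme mRMR on standardized columns Xs (local indices)."""
    n, p = Xs.shape
    k = min(k, p)
    selected = [int(np.argmax(F))]
    red_sum = np.zeros(p)
    while len(selected) < k:
        last = Xs[:, selected[-1]]
        r_last = np.abs(last @ Xs) / n  # |corr| with the newly selected column
        red_sum += r_last
        redundancy = red_sum / len(selected)
        score = F / np.maximum(redundancy, 1e-12)
        score[selected] = -np.inf
        # a feature perfectly correlated with a selected one adds nothing
        score[r_last >= 1.0 - 1e-9] = -np.inf
        nxt = int(np.argmax(score))
        if score[nxt] == -np.inf:
            break
        selected.append(nxt)
    return selected


def mrmr_select(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    feature_type_labels: Optional[np.ndarray] = None,
    task: str = "classification",
    mode: str = "per_type",
) -> np.ndarray:
    """Greedy minimal-redundancy-maximum-relevance selection.

    Relevance is the F-statistic of each feature against the target;
    redundancy the mean |Pearson r| with the already-selected features of the
    same type; the greedy score is their quotient.  With ``mode='per_type'``
    (the default) min(k, type size) features are selected within each feature
    type and the union returned, which attenuates the imbalance in family
    sizes; ``mode='global'`` selects k features overall.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    ok = sd > 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} zero-variance features")
    F_all = np.where(ok, _relevance(X, y, task), -np.inf)
    mean = X.mean(axis=0)
    Xs = (X - mean) / np.where(ok, sd, 1.0)
    if mode == "global" or feature_type_labels is None:
        groups = [np.where(ok)[0]]
    else:
        labels = np.asarray(feature_type_labels)
        groups = [
            np.where(ok & (labels == t))[0] for t in dict.fromkeys(labels)
        ]
    selected: list[int] = []
    for idx in groups:
        if idx.size == 0:
            continue
        local = _greedy_mrmr(Xs[:, idx], F_all[idx], k)
        selected.extend(idx[local])
    return np.array(sorted(selected), dtype=int)


# ---------------------------------------------------------------------------
# model pipelines


@dataclass
class FittedPipeline:
    """A standardizer + feature subset + fitted estimator (or majority fallback)."""

    mean: np.ndarray
    sd: np.ndarray
    features: np.ndarray  # column indices into the full matrix
    model: object
    task: str
    majority: Optional[float] = None  # set when the model degenerated

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.majority is not None:
            return np.full(X.shape[0], self.majority)
        Z = (X - self.mean) / self.sd
        return self.model.predict(Z[:, self.features])


def model_pipelines() -> dict[str, dict]:
    """The four classifier and two regressor pipeline contracts."""
    return {
        "svm": {"task": "classification", "selector": "rfe", "estimator": "linear SVC"},
        "logl2": {
            "task": "classification",
            "selector": "forward",
            "estimator": "logistic regression (L2)",
        },
        "logl1": {
            "task": "classification",
            "selector": "implicit (L1 sparsity)",
            "estimator": "logistic regression (L1)",
        },
        "rf": {"task": "classification", "selector": "none", "estimator": "random forest"},
        "lasso_reg": {"task": "regression", "selector": "implicit (L1)", "estimator": "lasso"},
        "ridge_reg": {"task": "regression", "selector": "none", "estimator": "ridge"},
    }


def _grid_for(model: str, grid: ModelGrid) -> list[dict]:
    """Hyperparameter combinations in tie-break preference order
    (stronger regularization / smaller model first)."""
    if model in ("logl1", "logl2"):
        return [{"C": float(c)} for c in np.sort(grid.logistic_C)]
    if model == "svm":
        return [{"C": float(c)} for c in np.sort(grid.svm_C)]
    if model == "rf":
        return [
            {"n_estimators": int(t), "max_depth": int(d)}
            for t in sorted(grid.rf_trees)
            for d in sorted(grid.rf_depth)
        ]
    if model in ("lasso_reg", "ridge_reg"):
        return [{"alpha": float(a)} for a in np.sort(grid.regression_alpha)[::-1]]
    raise ValueError(f"unknown model {model!r}")


def _forward_select(
    Z: np.ndarray, y: np.ndarray, make_est, cap: int
) -> list[int]:
    """Greedy sequential forward selection maximizing training balanced accuracy."""
    selected: list[int] = []
    best_score = -np.inf
    candidates = list(range(Z.shape[1]))
    for _ in range(min(cap, Z.shape[1])):
        step_best, step_feat = -np.inf, None
        for j in candidates:
            est = make_est()
            cols = selected + [j]
            est.fit(Z[:, cols], y)
            s = balanced_accuracy(y, est.predict(Z[:, cols]))
            if s > step_best:
                step_best, step_feat = s, j
        if step_feat is None or step_best <= best_score + 1e-12:
            break
        best_score = step_best
        selected.append(step_feat)
        candidates.remove(step_feat)
    return selected or [0]


def fit_pipeline(
    X: np.ndarray,
    y: np.ndarray,
    model: str,
    params: dict,
    mrmr_k: int,
    feature_types: Optional[np.ndarray],
    task: str,
    seed: int = 0,
    pool: Optional[np.ndarray] = None,
    grid: Optional[ModelGrid] = None,
) -> FittedPipeline:
    """Fit one full pipeline on a training partition.

    ``pool`` allows reuse of an mRMR selection already computed on the same
    training partition (never on data outside it).
    """
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    if pool is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pool = mrmr_select(X, y, mrmr_k, feature_types, task=task)
    Zp = Z[:, pool]
    cap = (grid or ModelGrid()).forward_cap
    target_k = min(mrmr_k, Zp.shape[1])

    majority = None
    if model == "logl1":
        est = LogisticRegression(
            l1_ratio=1.0, C=params["C"], solver="liblinear", max_iter=2000
        )
        est.fit(Zp, y)
        features = pool
        if np.all(est.coef_ == 0):
            vals, counts = np.unique(y, return_counts=True)
            majority = float(vals[np.argmax(counts)])
    elif model == "logl2":
        make = lambda: LogisticRegression(
            l1_ratio=0.0, C=params["C"], solver="liblinear", max_iter=2000
        )
        keep = _forward_select(Zp, y, make, cap)
        est = make()
        est.fit(Zp[:, keep], y)
        features = pool[keep]
    elif model == "svm":
        base = SVC(kernel="linear", C=params["C"])
        if Zp.shape[1] > target_k:
            rfe = RFE(base, n_features_to_select=target_k, step=1)
            rfe.fit(Zp, y)
            keep = np.where(rfe.support_)[0]
        else:
            keep = np.arange(Zp.shape[1])
        est = SVC(kernel="linear", C=params["C"])
        est.fit(Zp[:, keep], y)
        features = pool[keep]
    elif model == "rf":
        est = RandomForestClassifier(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            random_state=seed,
        )
        est.fit(Zp, y)
        features = pool
    elif model == "lasso_reg":
        est = Lasso(alpha=params["alpha"], max_iter=5000)
        est.fit(Zp, y)
        features = pool
        if np.all(est.coef_ == 0):
            majority = float(np.mean(y))
    elif model == "ridge_reg":
        est = Ridge(alpha=params["alpha"])
        est.fit(Zp, y)
        features = pool
    else:
        raise ValueError(f"unknown model {model!r}")

    if majority is not None:
        return FittedPipeline(mean, sd, features, None, task, majority=majority)
    # predict() passes Z[:, features]; each estimator was fit on exactly those
    # columns (the pool for implicit/no selectors, the kept subset otherwise)
    return FittedPipeline(mean, sd, features, est, task)


def _score(task: str, y_true, y_pred, train_mean: float) -> float:
    if task == "classification":
        return balanced_accuracy(y_true, y_pred)
    return -nmae(y_true, y_pred, train_mean)


@dataclass
class CVReport:
    """Per-outer-fold results of the repeated two-layer CV."""

    folds: pd.DataFrame  # repeat, fold, model, scores, chosen hyperparameters
    task: str
    repeats: int
    outer_k: int

    def summary(self) -> pd.DataFrame:
        """Mean and 95% CI of train/val/test scores per model, plus the
        one-sided baseline p (vs 0.5 for classifiers, vs 1.0 for regressors)."""
        rows = []
        for model, g in self.folds.groupby("model"):
            row = {"model": model, "n_folds": len(g)}
            for col in ("train_score", "val_score", "test_score"):
                vals = g[col].to_numpy()
                m = vals.mean()
                half = (
                    sstats.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(len(vals))
                    if len(vals) > 1
                    else np.nan
                )
                row[col] = m
                row[col + "_ci95"] = half
            test = g["test_score"].to_numpy()
            if len(test) < 6:
                row["baseline_p"] = np.nan  # signed-rank needs >= 6 folds
            elif self.task == "classification":
                row["baseline_p"] = baseline_test(test, 0.5, side="greater")
            else:
                row["baseline_p"] = baseline_test(-test, 1.0, side="less")
            rows.append(row)
        return pd.DataFrame(rows).set_index("model")

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "repeats": self.repeats,
            "outer_k": self.outer_k,
            "summary": json.loads(self.summary().to_json(orient="index")),
        }


def _fold_iter(n, k, labels, rng_seed):
    if labels is not None:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
        return cv.split(np.zeros(n), labels)
    cv = KFold(n_splits=k, shuffle=True, random_state=rng_seed)
    return cv.split(np.zeros(n))


def run_two_layer_cv(
    X: np.ndarray,
    y: np.ndarray,
    feature_types: Optional[np.ndarray] = None,
    models: tuple = ("logl1",),
    grid: Optional[ModelGrid] = None,
    repeats: int = 10,
    outer_k: int = 10,
    inner_k: int = 10,
    seed: int = 0,
    task: str = "classification",
    stratify: Optional[np.ndarray] = None,
) -> CVReport:
    """Repeated stratified two-layer (nested) cross-validation.

    Outer folds are evaluated exactly once on held-out subjects; the inner
    folds grid-search (mrmr_k x hyperparameters) with all standardization and
    feature selection refit inside each inner training partition.  Ties in
    mean validation score break toward smaller mrmr_k, then stronger
    regularization.  ``repeats x outer_k`` outer evaluations are produced.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    grid = grid or ModelGrid()
    if task == "classification":
        strat = y if stratify is None else stratify
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < outer_k:
            raise ValueError("need >= outer_k subjects per class for stratification")
    else:
        strat = stratify
        y = y.astype(float)

    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.generate_state(2 * repeats) % (2**31 - 1)
    records = []
    for rep in range(repeats):
        outer_seed = int(repeat_seeds[2 * rep])
        inner_seed = int(repeat_seeds[2 * rep + 1])
        for fold, (tr, te) in enumerate(_fold_iter(len(y), outer_k, strat, outer_seed)):
            Xtr, ytr = X[tr], y[tr]
            inner_strat = strat[tr] if strat is not None else None
            inner_splits = list(_fold_iter(len(tr), inner_k, inner_strat, inner_seed))
            # cache mRMR pools per (inner split, k): selection depends only on
            # the inner training partition
            pools: dict[tuple[int, int], np.ndarray] = {}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for si, (itr, _) in enumerate(inner_splits):
                    for k in grid.mrmr_k:
                        pools[(si, k)] = mrmr_select(
                            Xtr[itr], ytr[itr], k, feature_types, task=task
                        )
            for model in models:
                best = None  # (score, k, params)
                for k in sorted(grid.mrmr_k):
                    for params in _grid_for(model, grid):
                        val_scores = []
                        for si, (itr, iva) in enumerate(inner_splits):
                            fp = fit_pipeline(
                                Xtr[itr],
                                ytr[itr],
                                model,
                                params,
                                k,
                                feature_types,
                                task,
                                seed=inner_seed,
                                pool=pools[(si, k)],
                                grid=grid,
                            )
                            pred = fp.predict(Xtr[iva])
                            val_scores.append(
                                _score(task, ytr[iva], pred, float(np.mean(ytr[itr])))
                            )
                        mean_val = float(np.mean(val_scores))
                        if best is None or mean_val > best[0] + 1e-12:
                            best = (mean_val, k, params)
                _, best_k, best_params = best
                final = fit_pipeline(
                    Xtr, ytr, model, best_params, best_k, feature_types, task,
                    seed=outer_seed, grid=grid,
                )
                train_score = _score(task, ytr, final.predict(Xtr), float(np.mean(ytr)))
                test_score = _score(task, y[te], final.predict(X[te]), float(np.mean(ytr)))
                records.append(
                    {
                        "repeat": rep,
                        "fold": fold,
                        "model": model,
                        "mrmr_k": best_k,
                        "params": json.dumps(best_params),
                        "n_selected": int(len(final.features)),
                        "selected": json.dumps(np.asarray(final.features).tolist()),
                        "train_score": train_score,
                        "val_score": best[0],
                        "test_score": test_score,
                        "test_subjects": json.dumps(np.asarray(te).tolist()),
                        "train_subjects": json.dumps(np.asarray(tr).tolist()),
                    }
                )
    folds = pd.DataFrame.from_records(records)
    return CVReport(folds=folds, task=task, repeats=repeats, outer_k=outer_k)


def predict_from_table(
    ft,
    target: str = "group",
    models: tuple = ("logl1",),
    grid: Optional[ModelGrid] = None,
    feature_type: Optional[str] = None,
    **cv_kwargs,
) -> CVReport:
    """Run the CV framework on a FeatureTable.

    ``target='group'`` classifies CON vs ASD; 'aq', 'spq_vis' or 'spq_aud'
    regress the questionnaire score (stratified by group).  ``feature_type``
    restricts the feature pool to one of the 12 types.
    """
    types = ft.feature_types()
    X = ft.values.to_numpy(dtype=float)
    if feature_type is not None:
        m = types == feature_type
        if not m.any():
            raise ValueError(f"unknown feature type {feature_type!r}")
        X, types = X[:, m], types[m]
    groups = (ft.meta["group"] == "ASD").to_numpy().astype(int)
    if target == "group":
        return run_two_layer_cv(
            X, groups, types, models=models, grid=grid, task="classification", **cv_kwargs
        )
    y = ft.meta[target].to_numpy(dtype=float)
    return run_two_layer_cv(
        X, y, types, models=models, grid=grid, task="regression", stratify=groups,
        **cv_kwargs,
    )
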