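"""Univariate group comparisons: permutation test on means, Levene's test on
variances, BH-FDR within feature type.

The permutation test uses the absolute group-mean difference as its statistic
(two-sided).  All C(n, n_a) label arrangements are enumerated exhaustively
when there are no more of them than the requested Monte-Carlo count;
otherwise labels are shuffled ``n_perm`` times and the add-one estimate
p = (b + 1) / (n_perm + 1) guarantees p > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def permutation_mean_test(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10000, seed: int = 0
) -> float:
    """Two-sided permutation p-value for a difference in group means.

    Exhaustive over all label arrangements when feasible (p = b / n_total,
    counting the observed arrangement itself), Monte-Carlo with the add-one
    correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    n, na = pooled.size, x.size
    observed = abs(x.mean() - y.mean())
    total = comb(n, na)
    if total <= n_perm:
        count = 0
        pooled_sum = pooled.sum()
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            stat = abs(sa / na - (pooled_sum - sa) / (n - na))
            if stat >= observed - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(perm[:na].mean() - perm[na:].mean())
        if stat >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def permutation_mean_test_matrix(
    Xa: np.ndarray, Xb: np.ndarray, n_perm: int = 10000, seed: int = 0
) -> np.ndarray:
    """Columnwise permutation p-values sharing one set of label shuffles.

    Xa: n_a x p, Xb: n_b x p.  Vectorized over features: each permutation is a
    single reshuffling of subjects applied to every column, which preserves
    the across-feature correlation structure of the null.
    """
    Xa = np.atleast_2d(np.asarray(Xa, dtype=float))
    Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
    na, nb = Xa.shape[0], Xb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 subjects per group")
    pooled = np.vstack([Xa, Xb])
    n = na + nb
    observed = np.abs(Xa.mean(axis=0) - Xb.mean(axis=0))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(pooled.shape[1], dtype=np.int64)
    total = pooled.sum(axis=0)
    block = max(1, min(n_perm, 64_000_000 // max(pooled.shape[1], 1)))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        # b x n 0/1 membership matrix of permuted group-A assignments
        sel = np.zeros((b, n))
        for r in range(b):
            sel[r, rng.permutation(n)[:na]] = 1.0
        sa = sel @ pooled
        stat = np.abs(sa / na - (total[None, :] - sa) / nb)
        exceed += (stat >= observed[None, :] - 1e-12).sum(axis=0)
        done += b
    return (exceed + 1) / (n_perm + 1)


def levene_test(
    x: np.ndarray, y: np.ndarray, center: str = "mean"
) -> tuple[float, float]:
    """Classic Levene W on absolute deviations from the group center.

    ``center='median'`` gives the Brown-Forsythe variant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 values per group")
    w, p = sstats.levene(x, y, center=center)
    if not np.isfinite(w):
        raise ValueError("degenerate deviations")
    return float(w), float(p)


def significant_types(
    p_adj: np.ndarray,
    type_labels: np.ndarray,
    alpha: float = 0.05,
    flag_pct: float = 5.0,
) -> list[str]:
    """Feature types in which more than ``flag_pct`` % of features are
    significant after (within-type) FDR adjustment.

    This is the type-level decision rule used throughout the pipeline (the
    age screen applies the same >5% convention): isolated single-feature
    rejections — which the FDR guarantee permits at rate alpha per type even
    under a global null — do not declare a whole biomarker type significant.
    """
    p_adj = np.asarray(p_adj, dtype=float)
    types = np.asarray(type_labels)
    out = []
    for t in dict.fromkeys(types):
        m = types == t
        if 100.0 * np.mean(p_adj[m] < alpha) > flag_pct:
            out.append(t)
    return out


@dataclass
class StatReport:
    """Per-feature group statistics with within-type FDR adjustment."""

    mean_diff: pd.Series
    perm_p: pd.Series
    perm_p_adj: pd.Series
    levene_w: pd.Series
    levene_p: pd.Series
    levene_p_adj: pd.Series
    significant_mean: dict[str, int]
    significant_var: dict[str, int]
    flagged_mean_types: list[str]
    flagged_var_types: list[str]
    alpha: float = 0.05

    @property
    def n_significant_types(self) -> int:
        return len(set(self.flagged_mean_types) | set(self.flagged_var_types))

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "significant_mean_by_type": self.significant_mean,
            "significant_var_by_type": self.significant_var,
            "flagged_mean_types": list(self.flagged_mean_types),
            "flagged_var_types": list(self.flagged_var_types),
        }


def group_report(
    ft,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    levene_center: str = "mean",
) -> StatReport:
    """Permutation mean test + Levene variance test for every feature,
    BH-FDR within each of the 12 feature types."""
    groups = ft.meta["group"].to_numpy()
    a_mask = groups == "CON"
    b_mask = groups == "ASD"
    X = ft.values.to_numpy(dtype=float)
    Xa, Xb = X[a_mask], X[b_mask]
    cols = ft.values.columns
    types = ft.feature_types()

    mean_diff = Xa.mean(axis=0) - Xb.mean(axis=0)
    perm_p = permutation_mean_test_matrix(Xa, Xb, n_perm=n_perm, seed=seed)
    lev = [sstats.levene(Xa[:, j], Xb[:, j], center=levene_center) for j in range(X.shape[1])]
    lev_w = np.array([w for w, _ in lev])
    lev_p = np.array([p for _, p in lev])

    perm_adj = np.ones_like(perm_p)
    lev_adj = np.ones_like(lev_p)
    sig_mean: dict[str, int] = {}
    sig_var: dict[str, int] = {}
    for t in dict.fromkeys(types):
        m = types == t
        perm_adj[m] = fdr_bh(perm_p[m])
        lev_adj[m] = fdr_bh(np.nan_to_num(lev_p[m], nan=1.0))
        sig_mean[t] = int((perm_adj[m] < alpha).sum())
        sig_var[t] = int((lev_adj[m] < alpha).sum())

    return StatReport(
        mean_diff=pd.Series(mean_diff, index=cols),
        perm_p=pd.Series(perm_p, index=cols),
        perm_p_adj=pd.Series(perm_adj, index=cols),
        levene_w=pd.Series(lev_w, index=cols),
        levene_p=pd.Series(lev_p, index=cols),
        levene_p_adj=pd.Series(lev_adj, index=cols),
        significant_mean=sig_mean,
        significant_var=sig_var,
        flagged_mean_types=significant_types(perm_adj, types, alpha=alpha),
        flagged_var_types=significant_types(lev_adj, types, alpha=alpha),
        alpha=alpha,
    )
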