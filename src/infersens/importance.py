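"""Permutation feature importance (%IncMSE) and additive feature contributions.

Importance follows the out-of-bag convention of classical regression forests:
for each tree, the out-of-bag rows are predicted before and after permuting
one feature column, and

    %IncMSE(f) = 100 * mean_t(MSE_perm - MSE_oob) / mean_t(MSE_oob).

A constant column is unaffected by permutation and has importance 0 by
definition.  Medians are pooled across random seeds and outer resampling
folds.

Feature contributions decompose every forest prediction additively: walking a
tree from root to leaf, each split on feature f changes the running node mean;
that change is credited to f.  Summed over the path and averaged over trees,

    prediction(x) = baseline + sum_f contribution_f(x)

holds exactly (telescoping of node means), with baseline the mean of the
tree-root means.  A per-feature "goodness-of-visualization" R^2 quantifies how
much of a contribution's variance a 1-D smoother of contribution vs feature
value explains - low values flag interaction-driven features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from statsmodels.nonparametric.smoothers_lowess import lowess

from .featuresets import FeatureMatrix
from .model import CVPlan, RandomForest, fit_forest, split_patients


def permutation_importance(forest: RandomForest, X, y,
                           rng: np.random.Generator | int | None = None) -> pd.Series:
    """%IncMSE per feature from per-tree out-of-bag permutation.

    ``X``/``y`` must be the forest's training data (the retained per-tree OOB
    indices refer to its rows).
    """
    Xarr = np.asarray(X, dtype=float)
    yarr = np.asarray(y, dtype=float)
    names = list(X.columns) if hasattr(X, "columns") else [f"f{j}" for j in range(Xarr.shape[1])]
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    p = Xarr.shape[1]
    base_mse = np.zeros(len(forest.trees_))
    perm_mse = np.zeros((len(forest.trees_), p))
    constant = np.array([np.ptp(Xarr[:, j]) == 0 for j in range(p)])
    for t, (tree, oob) in enumerate(zip(forest.trees_, forest.oob_indices_)):
        if len(oob) == 0:
            base_mse[t] = np.nan
            perm_mse[t] = np.nan
            continue
        Xo = Xarr[oob]
        yo = yarr[oob]
        base_mse[t] = np.mean((yo - tree.predict(Xo)) ** 2)
        for j in range(p):
            if constant[j]:
                perm_mse[t, j] = base_mse[t]
                continue
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            perm_mse[t, j] = np.mean((yo - tree.predict(Xp)) ** 2)
    ok = np.isfinite(base_mse)
    denom = float(np.mean(base_mse[ok]))
    inc = 100.0 * np.nanmean(perm_mse[ok] - base_mse[ok, None], axis=0) / denom
    inc[constant] = 0.0
    return pd.Series(inc, index=names, name="pct_inc_mse")


@dataclass
class ImportanceTable:
    """%IncMSE per feature per (seed, outer fold), with pooled medians/IQR."""

    per_fold: pd.DataFrame  # columns: seed, fold, feature, pct_inc_mse

    def summary(self) -> pd.DataFrame:
        g = self.per_fold.groupby("feature").pct_inc_mse
        out = pd.DataFrame(
            {"median": g.median(), "q25": g.quantile(0.25), "q75": g.quantile(0.75)}
        )
        return out.sort_values("median", ascending=False)

    def per_seed_ranks(self) -> pd.DataFrame:
        """Feature rank (1 = most important) by per-seed median %IncMSE."""
        med = self.per_fold.groupby(["seed", "feature"]).pct_inc_mse.median().unstack()
        return med.rank(axis=1, ascending=False)

    def to_csv(self, path) -> None:
        self.per_fold.to_csv(path, index=False)


def importance_over_folds(fm: FeatureMatrix, plan: CVPlan | None = None,
                          mtry: int | None = None) -> ImportanceTable:
    """Permutation importance on the outer-fold training forests.

    For every (seed, outer fold), a forest is fit on the outer training rows
    (mtry defaults to the smallest value of the plan's tuning grid) and OOB
    permutation importance is computed; results are pooled across seeds and
    folds.
    """
    plan = plan or CVPlan()
    X = fm.X
    y = fm.y.to_numpy(dtype=float)
    patients = fm.keys.patient_id.unique()
    m = mtry if mtry is not None else plan.grid_for(fm.set_id, X.shape[1])[0]
    rows = []
    for seed in plan.seeds:
        assign = split_patients(patients, plan.outer_folds, seed * 1000)
        fold_of_row = fm.keys.patient_id.map(assign).to_numpy()
        for outer in range(plan.outer_folds):
            train = fold_of_row != outer
            forest = fit_forest(
                X.to_numpy(float)[train], y[train], mtry=m, n_trees=plan.n_trees,
                rng=seed * 10_000 + outer, min_samples_leaf=plan.min_samples_leaf,
            )
            imp = permutation_importance(
                forest, X.loc[train], y[train],
                rng=np.random.default_rng(seed * 10_000 + outer + 1),
            )
            for feat, val in imp.items():
                rows.append({"seed": seed, "fold": outer, "feature": feat,
                             "pct_inc_mse": float(val)})
    return ImportanceTable(per_fold=pd.DataFrame(rows))


@dataclass
class ContributionSet:
    """Additive decomposition of forest predictions.

    ``baseline + contributions.sum(axis=1) == forest.predict(X)`` row-wise.
    """

    baseline: float
    contributions: pd.DataFrame

    def predictions(self) -> np.ndarray:
        return self.baseline + self.contributions.sum(axis=1).to_numpy()


def feature_contributions(forest: RandomForest, X) -> ContributionSet:
    """forestFloor-style contributions: credit each split's change in node
    mean to the split feature, averaged over trees."""
    Xarr = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(Xarr)):
        raise ValueError("observations contain missing/non-finite feature values")
    names = list(X.columns) if hasattr(X, "columns") else [f"f{j}" for j in range(Xarr.shape[1])]
    n, p = Xarr.shape
    total = np.zeros((n, p))
    baseline = 0.0
    for tree in forest.trees_:
        t = tree.tree_
        values = t.value.reshape(-1)
        baseline += values[0]
        n_nodes = t.node_count
        parent = np.full(n_nodes, -1)
        for j in range(n_nodes):
            for child in (t.children_left[j], t.children_right[j]):
                if child != -1:
                    parent[child] = j
        nonroot = np.arange(n_nodes)[parent >= 0]
        delta = values[nonroot] - values[parent[nonroot]]
        feat = t.feature[parent[nonroot]]
        credit = sparse.csr_matrix(
            (delta, (nonroot, feat)), shape=(n_nodes, p)
        )
        dp = tree.decision_path(Xarr)
        total += dp @ credit
    k = len(forest.trees_)
    return ContributionSet(
        baseline=baseline / k,
        contributions=pd.DataFrame(total / k, columns=names),
    )


def goodness_of_visualization(contribution, feature_values, frac: float = 0.3) -> float:
    """R^2 of a 1-D local-regression smoother of contribution vs feature value.

    Low values indicate that a feature's contribution depends on other
    features (interactions).  Zero-variance contributions give R^2 = 1.
    The default span (0.3) is small enough that a noiseless smooth
    contribution-vs-feature relationship scores R^2 > 0.99.
    """
    c = np.asarray(contribution, dtype=float)
    x = np.asarray(feature_values, dtype=float)
    if len(c) < 10:
        raise ValueError("need at least 10 observations")
    var_c = float(np.var(c))
    if var_c == 0:
        return 1.0
    fitted = lowess(c, x, frac=frac, xvals=x)
    resid = c - fitted
    return float(1.0 - np.var(resid) / var_c)
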