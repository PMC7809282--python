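"""Seeded, nested, patient-wise cross-validated random-forest regression.

The learner is a random forest: bagged regression trees with ``mtry``
candidate predictors per split.  Bagging is explicit (per-tree bootstrap
indices are retained) so that downstream analyses can use out-of-bag rows per
tree (permutation importance) and walk node means (feature contributions);
the individual trees are scikit-learn ``DecisionTreeRegressor`` objects.

Accuracy is estimated by nested resampling: an outer 5-fold patient-wise
cross-validation measures accuracy, and within each outer training set an
inner 5-fold patient-wise cross-validation tunes ``mtry`` (minimizing inner
MAE, smallest value winning ties).  The whole procedure is repeated over a
list of random seeds; metrics are computed per seed and then averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .featuresets import FeatureMatrix, null_predict

log = logging.getLogger(__name__)

DEFAULT_MTRY_GRID = {1: (6, 14, 22), 2: (6, 14, 22), 3: (6, 14, 22),
                     4: (120, 160, 200), 5: (120, 160, 200)}


class RandomForest:
    """Bagged regression trees with retained bootstrap/OOB bookkeeping.

    Attributes after ``fit``: ``trees_`` (fitted DecisionTreeRegressor list),
    ``bootstrap_indices_`` and ``oob_indices_`` (per-tree row indices into the
    training data).
    """

    def __init__(self, n_trees: int = 500, mtry: int | None = None,
                 min_samples_leaf: int = 5, random_state: int | None = None):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y) -> "RandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        mtry = self.mtry if self.mtry is not None else max(p // 3, 1)
        if mtry > p:
            raise ValueError(f"mtry={mtry} exceeds number of predictors p={p}")
        rng = np.random.default_rng(self.random_state)
        self.n_features_ = p
        self.trees_, self.bootstrap_indices_, self.oob_indices_ = [], [], []
        all_rows = np.arange(n)
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(all_rows, idx, assume_unique=False)
            tree = DecisionTreeRegressor(
                max_features=mtry,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(2**31)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            self.bootstrap_indices_.append(idx)
            self.oob_indices_.append(oob)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for tree in self.trees_:
            out += tree.predict(X)
        return out / len(self.trees_)


def fit_forest(X, y, mtry: int, n_trees: int = 500, rng: int | None = None,
               min_samples_leaf: int = 5) -> RandomForest:
    """Fit a random forest with ``mtry`` candidate predictors per split."""
    return RandomForest(
        n_trees=n_trees, mtry=mtry, min_samples_leaf=min_samples_leaf, random_state=rng
    ).fit(X, y)


@dataclass
class CVPlan:
    """Resampling plan: 7 seeds, 5 outer / 5 inner patient-wise folds, and the
    mtry tuning grid ({6, 14, 22} for sets 1-3, {120, 160, 200} for 4/5;
    candidates larger than p are clamped to p)."""

    seeds: tuple[int, ...] = tuple(range(7))
    outer_folds: int = 5
    inner_folds: int = 5
    mtry_grid: tuple[int, ...] | None = None  # default depends on feature-set
    n_trees: int = 500
    min_samples_leaf: int = 5

    def grid_for(self, set_id: int, p: int) -> list[int]:
        grid = self.mtry_grid if self.mtry_grid is not None else DEFAULT_MTRY_GRID[set_id]
        return sorted({min(int(m), p) for m in grid})


def split_patients(patient_ids, k: int, rng) -> dict:
    """Assign patients to k folds of near-equal size (sizes differ by <= 1).

    ``rng`` is a seed or ``numpy.random.Generator``; the assignment is
    deterministic given the seed.
    """
    ids = np.asarray(sorted(set(patient_ids)))
    if k > len(ids):
        raise ValueError(f"cannot split {len(ids)} patients into {k} folds")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    perm = rng.permutation(len(ids))
    folds = np.empty(len(ids), dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = fold
    return dict(zip(ids.tolist(), folds.tolist()))


@dataclass
class PredictionSet:
    """Out-of-fold predictions: one row per (seed, outer fold, evaluation row),
    with observed/predicted loss, grouping keys and the tuned mtry."""

    frame: pd.DataFrame

    def mae_per_seed(self) -> pd.Series:
        return self.frame.groupby("seed").apply(
            lambda g: float(np.mean(np.abs(g.observed - g.predicted))), include_groups=False
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _mae(a, b) -> float:
    return float(np.mean(np.abs(np.asarray(a) - np.asarray(b))))


def _patient_folds_with_eval(fm: FeatureMatrix, patients, k, seed, max_tries=10):
    """Patient-wise folds; re-split with a seed offset if any fold has zero
    evaluation rows (degenerate for error estimation)."""
    pat = fm.keys.patient_id.to_numpy()
    emask = fm.eval_mask.to_numpy()
    for off in range(max_tries):
        assign = split_patients(patients, k, seed + off)
        fold_of_row = np.vectorize(assign.get)(pat)
        if all(np.any(emask & (fold_of_row == f)) for f in range(k)):
            if off:
                log.warning("re-split patients with seed offset %d (empty eval fold)", off)
            return assign, fold_of_row
    raise RuntimeError("could not build folds with non-empty evaluation rows")


def nested_cv(fm: FeatureMatrix, plan: CVPlan | None = None) -> PredictionSet:
    """Nested patient-wise cross-validation of a random-forest regressor.

    Per seed: 5 outer folds; within each outer training set an inner 5-fold
    CV selects mtry by minimal inner MAE (computed on evaluation rows only;
    smallest mtry wins ties); a forest with the winning mtry is refit on the
    full outer training set and predicts the outer-fold evaluation rows.
    """
    plan = plan or CVPlan()
    X = fm.X.to_numpy(dtype=float)
    y = fm.y.to_numpy(dtype=float)
    emask = fm.eval_mask.to_numpy()
    patients = fm.keys.patient_id.unique()
    grid = plan.grid_for(fm.set_id, X.shape[1])

    records = []
    for seed in plan.seeds:
        assign, fold_of_row = _patient_folds_with_eval(fm, patients, plan.outer_folds, seed * 1000)
        for outer in range(plan.outer_folds):
            test_rows = fold_of_row == outer
            train_rows = ~test_rows
            train_pats = [p for p, f in assign.items() if f != outer]
            if len(grid) > 1:
                inner_assign = split_patients(train_pats, plan.inner_folds, seed * 1000 + outer + 1)
                inner_fold = np.vectorize(lambda p: inner_assign.get(p, -1))(
                    fm.keys.patient_id.to_numpy()
                )
                scores = {m: [] for m in grid}
                for inner in range(plan.inner_folds):
                    fit_rows = train_rows & (inner_fold != inner)
                    val_rows = train_rows & (inner_fold == inner) & emask
                    if not val_rows.any():
                        continue
                    for m in grid:
                        forest = fit_forest(
                            X[fit_rows], y[fit_rows], mtry=m, n_trees=plan.n_trees,
                            rng=seed * 10_000 + outer * 100 + inner,
                            min_samples_leaf=plan.min_samples_leaf,
                        )
                        scores[m].append(_mae(y[val_rows], forest.predict(X[val_rows])))
                mean_scores = {m: float(np.mean(v)) for m, v in scores.items() if v}
                best = min(mean_scores, key=lambda m: (mean_scores[m], m))
            else:
                best = grid[0]
            forest = fit_forest(
                X[train_rows], y[train_rows], mtry=best, n_trees=plan.n_trees,
                rng=seed * 10_000 + outer * 100 + 99,
                min_samples_leaf=plan.min_samples_leaf,
            )
            score_rows = test_rows & emask
            pred = forest.predict(X[score_rows])
            block = fm.keys.loc[score_rows, ["patient_id", "eye_id", "visit", "test_index",
                                             "point_id", "x_deg", "y_deg"]].copy()
            block["seed"] = seed
            block["fold"] = outer
            block["mtry"] = best
            block["observed"] = y[score_rows]
            block["predicted"] = pred
            records.append(block.reset_index(drop=True))
    return PredictionSet(frame=pd.concat(records, ignore_index=True))


def null_cv(fm: FeatureMatrix, plan: CVPlan | None = None) -> PredictionSet:
    """Out-of-fold null-model predictions on the same resampling plan.

    Sets 1-3 predict the training-fold mean loss; sets 4/5 predict each test
    eye's mean loss over its 13 every-2-degree seed loci.
    """
    plan = plan or CVPlan()
    y = fm.y.to_numpy(dtype=float)
    emask = fm.eval_mask.to_numpy()
    patients = fm.keys.patient_id.unique()
    records = []
    for seed in plan.seeds:
        assign, fold_of_row = _patient_folds_with_eval(fm, patients, plan.outer_folds, seed * 1000)
        for outer in range(plan.outer_folds):
            test_rows = fold_of_row == outer
            train = fm.subset(~test_rows)
            test = fm.subset(test_rows)
            pred = null_predict(fm.set_id, train, test)
            keep = test.eval_mask.to_numpy()
            block = test.keys.loc[keep, ["patient_id", "eye_id", "visit", "test_index",
                                         "point_id", "x_deg", "y_deg"]].copy()
            block["seed"] = seed
            block["fold"] = outer
            block["mtry"] = 0
            block["observed"] = test.y.to_numpy()[keep]
            block["predicted"] = np.asarray(pred)[keep]
            records.append(block.reset_index(drop=True))
    return PredictionSet(frame=pd.concat(records, ignore_index=True))
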