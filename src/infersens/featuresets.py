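"""Predictor matrices for the five feature-sets, and their null models.

Feature-sets (p = number of predictors):

1. imaging features only (p = 20),
2. + retest-reliability indicators: false-positive responses, mean reaction
   time (p = 22),
3. + functional/demographic covariates: fixation stability, BCVA, ERG group,
   age-of-onset category (p = 26; the two categorical scales enter as ordered
   integers),
4. set-3 predictors + measured sensitivity loss at the 7 every-4-degree
   horizontal-meridian seed loci (broadcast within eye x visit) + one-hot
   eye-ID columns (p = 26 + 7 + n_eyes),
5. as 4 but with the 13 every-2-degree seed loci (p = 26 + 13 + n_eyes).

For sets 4/5 the seed-locus rows are excluded from the evaluation mask (their
own measurements are predictors, so they are never scored).  The null model
"predicts" the training-set mean loss (sets 1-3) or, for sets 4/5, each test
eye's mean loss over its 13 every-2-degree seed loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enface import FEATURE_NAMES

IMAGING_COLS = list(FEATURE_NAMES)
RELIABILITY_COLS = ["false_positive_responses", "mean_reaction_time_ms"]
COVARIATE_COLS = ["fixation_stability", "bcva_logmar", "erg_group", "onset_category"]
KEY_COLS = ["patient_id", "eye_id", "visit", "test_index", "point_id", "x_deg", "y_deg"]

TARGET_COL = "sensitivity_loss"


@dataclass
class FeatureMatrix:
    """Model-ready predictor block for one feature-set.

    ``X`` holds only predictor columns; ``y`` is sensitivity loss (dB);
    ``keys`` carries the hierarchy/grouping columns (plus, for sets 4/5, the
    per-eye mean over the 13 every-2-degree seed loci used by the null model);
    ``eval_mask`` flags rows eligible for error computation.
    """

    set_id: int
    X: pd.DataFrame
    y: pd.Series
    keys: pd.DataFrame
    eval_mask: pd.Series

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, row_mask) -> "FeatureMatrix":
        row_mask = np.asarray(row_mask)
        return FeatureMatrix(
            set_id=self.set_id,
            X=self.X.loc[row_mask].reset_index(drop=True),
            y=self.y.loc[row_mask].reset_index(drop=True),
            keys=self.keys.loc[row_mask].reset_index(drop=True),
            eval_mask=self.eval_mask.loc[row_mask].reset_index(drop=True),
        )

    def assert_no_leakage(self) -> None:
        """Audit: no evaluation row may carry its own measured loss among its
        predictors, and the target column never appears in X."""
        if TARGET_COL in self.X.columns:
            raise AssertionError("target column present among predictors")
        seed_cols = [c for c in self.X.columns if c.startswith("seed_loss_")]
        if seed_cols:
            seed_pids = {c.removeprefix("seed_loss_") for c in seed_cols}
            bad = self.keys.loc[self.eval_mask.to_numpy(), "point_id"].isin(seed_pids)
            if bad.any():
                raise AssertionError(
                    "evaluation rows located at seed loci (own target leaks into predictors)"
                )


def _seed_losses(data: pd.DataFrame, seed_ids: list[str]) -> pd.DataFrame:
    """Per (eye, visit): measured loss at each seed locus, from the first test
    of the session.  Errors if any eye misses a seed locus."""
    first = data[data.test_index == data.groupby(["eye_id", "visit"]).test_index.transform("min")]
    wide = first.pivot_table(
        index=["eye_id", "visit"], columns="point_id", values=TARGET_COL, aggfunc="first"
    )
    missing = [
        (eye, pid)
        for pid in seed_ids
        if pid not in wide.columns
        for eye in wide.index.get_level_values(0).unique()
    ] + [
        (idx, pid)
        for pid in seed_ids
        if pid in wide.columns
        for idx in wide.index[wide[pid].isna()]
    ]
    if missing:
        raise ValueError(f"missing seed-locus measurements: {missing[:5]}")
    return wide[seed_ids]


def build(set_id: int, data: pd.DataFrame, grid) -> FeatureMatrix:
    """Assemble the FeatureMatrix for one feature-set from standardized data.

    ``data`` is a standardized point-record table (imaging columns are
    z-scores, ``sensitivity_loss`` present); ``grid`` supplies the seed-locus
    ids for sets 4/5.
    """
    if set_id not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown feature-set id {set_id!r}")
    cols = list(IMAGING_COLS)
    if set_id >= 2:
        cols += RELIABILITY_COLS
    if set_id >= 3:
        cols += COVARIATE_COLS
    X = data[cols].astype(float).reset_index(drop=True)
    keys = data[KEY_COLS].reset_index(drop=True)
    y = data[TARGET_COL].astype(float).reset_index(drop=True)
    eval_mask = pd.Series(True, index=X.index, name="eval_mask")

    if set_id in (4, 5):
        seed_ids = grid.meridian_ids(spacing=4 if set_id == 4 else 2)
        seed13_ids = grid.meridian_ids(spacing=2)
        seeds = _seed_losses(data, seed_ids)
        seeds13_mean = _seed_losses(data, seed13_ids).mean(axis=1).rename("seed13_mean")
        idx = pd.MultiIndex.from_frame(keys[["eye_id", "visit"]])
        seed_block = seeds.reindex(idx).reset_index(drop=True)
        seed_block.columns = [f"seed_loss_{pid}" for pid in seed_block.columns]
        X = pd.concat([X, seed_block], axis=1)
        keys = keys.assign(seed13_mean=seeds13_mean.reindex(idx).to_numpy())
        onehot = pd.get_dummies(keys.eye_id, prefix="eye", dtype=float)
        X = pd.concat([X, onehot], axis=1)
        eval_mask = ~keys.point_id.isin(seed_ids)
        eval_mask.name = "eval_mask"

    return FeatureMatrix(set_id=set_id, X=X, y=y, keys=keys, eval_mask=eval_mask)


def null_predict(set_id: int, train: FeatureMatrix, test: FeatureMatrix) -> np.ndarray:
    """Null-model predictions for the test rows (all rows, masked or not).

    Sets 1-3: the training-set mean sensitivity loss.  Sets 4/5: each test
    eye's mean loss over its 13 every-2-degree seed loci.
    """
    if len(train.y) == 0:
        raise ValueError("empty training set")
    if set_id in (1, 2, 3):
        return np.full(len(test.y), float(train.y[train.eval_mask.to_numpy()].mean()))
    if "seed13_mean" not in test.keys.columns:
        raise ValueError("feature matrix lacks per-eye seed means (build sets 4/5 first)")
    return test.keys.seed13_mean.to_numpy(dtype=float)
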