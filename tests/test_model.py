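"""Patient-wise splits, forest behaviour and nested cross-validation."""

import numpy as np
import pandas as pd
import pytest

from infersens import featuresets as fs
from infersens import model as mdl


def _make_fm(X, y, patients, set_id=1):
    n = len(y)
    keys = pd.DataFrame(
        {"patient_id": patients, "eye_id": [f"{p}_OD" for p in patients],
         "visit": 1, "test_index": 1, "point_id": [f"p{i}" for i in range(n)],
         "x_deg": 0.0, "y_deg": 0.0}
    )
    return fs.FeatureMatrix(
        set_id=set_id, X=pd.DataFrame(X).add_prefix("f"), y=pd.Series(y, dtype=float),
        keys=keys, eval_mask=pd.Series([True] * n),
    )


def _noise_fm(rng, n_patients=10, rows_per_patient=20, p=5):
    n = n_patients * rows_per_patient
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    patients = np.repeat([f"P{i}" for i in range(n_patients)], rows_per_patient)
    return _make_fm(X, y, patients)


class TestSplitPatients:
    def test_even_split(self):
        assign = mdl.split_patients([f"P{i}" for i in range(10)], 5, 0)
        sizes = pd.Series(assign).value_counts()
        assert (sizes == 2).all()

    def test_sizes_differ_by_at_most_one(self):
        assign = mdl.split_patients([f"P{i}" for i in range(13)], 5, 3)
        sizes = pd.Series(assign).value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_deterministic_given_seed(self):
        ids = [f"P{i}" for i in range(20)]
        assert mdl.split_patients(ids, 5, 7) == mdl.split_patients(ids, 5, 7)

    def test_too_many_folds(self):
        with pytest.raises(ValueError):
            mdl.split_patients(["a", "b"], 3, 0)


class TestRandomForest:
    def test_duplicated_point_single_tree_predicts_its_value(self):
        X = np.tile([[1.0, 2.0]], (30, 1))
        y = np.full(30, 7.5)
        f = mdl.fit_forest(X, y, mtry=1, n_trees=1, rng=0, min_samples_leaf=1)
        assert f.predict([[1.0, 2.0]])[0] == pytest.approx(7.5)

    def test_predictions_within_training_range(self, rng):
        X = rng.normal(size=(200, 4))
        y = rng.normal(size=200) * 10
        f = mdl.fit_forest(X, y, mtry=2, n_trees=25, rng=1)
        pred = f.predict(rng.normal(size=(100, 4)) * 3)
        assert pred.min() >= y.min() - 1e-9 and pred.max() <= y.max() + 1e-9

    def test_mtry_exceeding_p_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError, match="mtry"):
            mdl.fit_forest(X, np.zeros(20), mtry=4, n_trees=2, rng=0)

    def test_bagged_trees_are_seed_stable(self, rng):
        """mtry = p: predictions of two seeds strongly rank-correlated on a
        smooth function."""
        from scipy.stats import spearmanr

        X = rng.uniform(-2, 2, size=(300, 3))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + 0.1 * rng.normal(size=300)
        Xt = rng.uniform(-2, 2, size=(150, 3))
        p1 = mdl.fit_forest(X, y, mtry=3, n_trees=60, rng=1).predict(Xt)
        p2 = mdl.fit_forest(X, y, mtry=3, n_trees=60, rng=2).predict(Xt)
        assert spearmanr(p1, p2).statistic > 0.95

    def test_oob_indices_disjoint_from_bootstrap(self, rng):
        X = rng.normal(size=(50, 2))
        f = mdl.fit_forest(X, rng.normal(size=50), mtry=1, n_trees=5, rng=0)
        for idx, oob in zip(f.bootstrap_indices_, f.oob_indices_):
            assert len(np.intersect1d(idx, oob)) == 0


class TestNestedCV:
    def test_constant_target_gives_zero_mae(self, rng):
        fm = _noise_fm(rng)
        fm.y[:] = 4.2
        plan = mdl.CVPlan(seeds=(0,), n_trees=10, mtry_grid=(2,))
        ps = mdl.nested_cv(fm, plan)
        assert ps.mae_per_seed().iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_each_eval_row_predicted_once_per_seed(self, rng):
        fm = _noise_fm(rng)
        plan = mdl.CVPlan(seeds=(0, 1), n_trees=5, mtry_grid=(2,))
        ps = mdl.nested_cv(fm, plan)
        counts = ps.frame.groupby(["seed", "point_id"]).size()
        assert (counts == 1).all()
        assert len(ps.frame) == 2 * len(fm.y)

    def test_patient_never_split_across_folds(self, rng):
        fm = _noise_fm(rng)
        plan = mdl.CVPlan(seeds=(0,), n_trees=5, mtry_grid=(2,))
        ps = mdl.nested_cv(fm, plan)
        assert (ps.frame.groupby("patient_id").fold.nunique() == 1).all()

    def test_relabeling_test_patient_does_not_change_their_predictions(self, rng):
        """Train/test isolation: a held-out patient's targets never influence
        their own out-of-fold predictions."""
        fm = _noise_fm(rng)
        plan = mdl.CVPlan(seeds=(0,), n_trees=8, mtry_grid=(2, 3))
        base = mdl.nested_cv(fm, plan).frame.set_index(["patient_id", "point_id"])
        victim = fm.keys.patient_id.iloc[0]
        fm2 = fs.FeatureMatrix(
            set_id=fm.set_id, X=fm.X.copy(), y=fm.y.copy(), keys=fm.keys.copy(),
            eval_mask=fm.eval_mask.copy(),
        )
        rows = (fm2.keys.patient_id == victim).to_numpy()
        fm2.y[rows] = rng.normal(size=rows.sum()) * 100
        alt = mdl.nested_cv(fm2, plan).frame.set_index(["patient_id", "point_id"])
        np.testing.assert_allclose(
            base.loc[victim].predicted.to_numpy(), alt.loc[victim].predicted.to_numpy()
        )

    def test_no_spurious_skill_on_pure_noise(self, rng):
        """Cross-validated model MAE >= null MAE - 2 x between-seed SE."""
        fm = _noise_fm(rng, n_patients=12, rows_per_patient=15)
        plan = mdl.CVPlan(seeds=(0, 1, 2), n_trees=20, mtry_grid=(2, 4))
        model_mae = mdl.nested_cv(fm, plan).mae_per_seed()
        null_mae = mdl.null_cv(fm, plan).mae_per_seed()
        eps = 2 * float(np.std(model_mae - null_mae, ddof=1)) / np.sqrt(len(model_mae))
        assert model_mae.mean() >= null_mae.mean() - max(eps, 0.02)

    def test_signal_beats_null(self, rng):
        """Strong structure: cross-validated MAE well below the null MAE."""
        n_patients, rows = 12, 25
        n = n_patients * rows
        X = rng.normal(size=(n, 4))
        y = 6.0 * X[:, 0] + 4.0 * X[:, 1] + 0.3 * rng.normal(size=n)
        patients = np.repeat([f"P{i}" for i in range(n_patients)], rows)
        fm = _make_fm(X, y, patients)
        plan = mdl.CVPlan(seeds=(0,), n_trees=30, mtry_grid=(2,))
        model_mae = mdl.nested_cv(fm, plan).mae_per_seed().mean()
        null_mae = mdl.null_cv(fm, plan).mae_per_seed().mean()
        assert model_mae < 0.5 * null_mae

    def test_inner_selection_never_worse_than_fixed_mtry(self, rng):
        """Optimization-bias guard: tuned forests do at least as well (within
        Monte-Carlo error) as the worst fixed grid value."""
        n_patients, rows = 10, 20
        n = n_patients * rows
        X = rng.normal(size=(n, 6))
        y = 3 * X[:, 0] + rng.normal(size=n)
        patients = np.repeat([f"P{i}" for i in range(n_patients)], rows)
        fm = _make_fm(X, y, patients)
        tuned = mdl.nested_cv(fm, mdl.CVPlan(seeds=(0, 1), n_trees=15, mtry_grid=(1, 6)))
        fixed = [
            mdl.nested_cv(fm, mdl.CVPlan(seeds=(0, 1), n_trees=15, mtry_grid=(m,)))
            for m in (1, 6)
        ]
        worst_fixed = max(f.mae_per_seed().mean() for f in fixed)
        assert tuned.mae_per_seed().mean() <= worst_fixed * 1.1

    def test_mtry_grid_clamped_to_p(self):
        plan = mdl.CVPlan()
        assert plan.grid_for(4, p=60) == [60]
        assert plan.grid_for(1, p=20) == [6, 14, 20]
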