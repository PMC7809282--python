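"""Stimulus grid, staircase measurement model, ground-truth map and cohorts."""

import numpy as np
import pandas as pd
import pytest

from infersens import simulate as sim


class TestGrid:
    def test_default_grid_has_50_points(self, grid50):
        assert grid50.n_points == 50
        assert grid50.points.point_id.is_unique

    def test_meridian_subsets(self, grid50):
        assert len(grid50.meridian_ids(spacing=2)) == 13
        assert len(grid50.meridian_ids(spacing=4)) == 7
        x4 = sorted(
            grid50.points.set_index("point_id").loc[grid50.meridian_ids(4), "x_deg"]
        )
        assert x4 == [-14, -10, -6, -2, 2, 6, 10]

    def test_missing_meridian_locus_rejected(self):
        with pytest.raises(ValueError, match="meridian"):
            sim.make_grid(sim.GridSpec(meridian_x=(-14.0, -12.0, 0.0)))

    def test_duplicate_points_rejected(self):
        spec = sim.GridSpec(off_meridian={2.0: (0.0, 0.0)})
        with pytest.raises(ValueError, match="duplicate"):
            sim.make_grid(spec)


class TestStaircase:
    def test_dynamic_range_is_36_db(self):
        p = sim.StaircaseParams()
        assert p.db_ceiling - p.db_floor == 36.0
        with pytest.raises(ValueError):
            sim.StaircaseParams(db_ceiling=30.0)

    def test_steep_slope_recovers_threshold_within_2_db(self):
        """With a near-step psychometric function and no lapses, the 4-2
        staircase lands within one fine step of the true threshold."""
        p = sim.StaircaseParams(
            psychometric_sd_db=1e-9, false_positive_rate=0.0, false_negative_rate=0.0
        )
        rng = np.random.default_rng(0)
        for true in np.arange(0.25, 35.8, 0.5):
            measured = sim.run_staircase(true, p, rng)
            assert abs(measured - true) <= 2.0

    def test_always_seen_returns_ceiling(self):
        p = sim.StaircaseParams(false_positive_rate=1.0, false_negative_rate=0.0)
        assert sim.run_staircase(10.0, p, np.random.default_rng(0)) == p.db_ceiling

    def test_never_seen_coded_as_floor(self):
        p = sim.StaircaseParams(
            psychometric_sd_db=1e-9, false_positive_rate=0.0, false_negative_rate=0.0
        )
        assert sim.run_staircase(-10.0, p, np.random.default_rng(0)) == p.db_floor

    def test_retest_differences_are_symmetric(self):
        """test1 - test2 should have mean 0 within Monte-Carlo error."""
        p = sim.StaircaseParams()
        rng = np.random.default_rng(7)
        d = np.array(
            [sim.run_staircase(18.0, p, rng) - sim.run_staircase(18.0, p, rng)
             for _ in range(10_000)]
        )
        assert abs(d.mean()) < 3 * d.std() / np.sqrt(len(d))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            sim.StaircaseParams(false_positive_rate=0.7, false_negative_rate=0.7)


class TestGroundTruthMap:
    def test_zero_deficit_gives_normative_sensitivity(self):
        gt = sim.GroundTruthMap()
        z = {l: np.zeros(3) for l in sim.LAYERS}
        out = sim.true_sensitivity(z, gt, normative_db=np.array([30.0, 25.0, 20.0]))
        np.testing.assert_allclose(out, [30.0, 25.0, 20.0])

    def test_linear_link_hand_example(self):
        """w_ISOS=6, w_RPE=4, z_ISOS=-2, z_RPE=-1 at normative 30 dB -> 14 dB."""
        gt = sim.GroundTruthMap(
            weights={"ISOS": 6.0, "RPE": 4.0, "ONL": 0.0, "FR": 0.0, "IR": 0.0},
            link="linear",
        )
        z = {"ISOS": -2.0, "RPE": -1.0, "ONL": 0.0, "FR": 0.0, "IR": 0.0}
        assert sim.true_sensitivity(z, gt, 30.0) == pytest.approx(14.0)

    def test_extreme_deficit_clamps_to_floor(self):
        gt = sim.GroundTruthMap(link="linear")
        z = {l: 0.0 for l in sim.LAYERS} | {"ISOS": -1e9}
        assert sim.true_sensitivity(z, gt, 30.0) == gt.db_floor

    def test_monotone_in_each_layer_z(self, rng):
        gt = sim.GroundTruthMap()
        base = {l: rng.normal(0, 2, size=50) for l in sim.LAYERS}
        s0 = sim.true_sensitivity(base, gt, 28.0)
        for layer in sim.LAYERS:
            bumped = {k: v.copy() for k, v in base.items()}
            bumped[layer] = bumped[layer] + 0.5
            s1 = sim.true_sensitivity(bumped, gt, 28.0)
            assert np.all(s1 >= s0 - 1e-12)

    def test_weight_ordering_enforced(self):
        with pytest.raises(ValueError, match="w_ISOS"):
            sim.GroundTruthMap(weights={"ISOS": 1.0, "RPE": 2.0, "ONL": 0.1, "FR": 0.1, "IR": 0.1})


class TestSynthStructure:
    def test_zero_severity_patient_within_control_range(self, grid13):
        cfg = sim.CohortConfig(
            n_patients=12, n_controls=1, eyes_per_patient=2,
            severity_alpha=1e-6, severity_beta=1e6, seed=3,
        )
        df = sim.synth_structure(cfg, grid13, np.random.default_rng(3))
        assert (df.severity < 0.01).all()
        ok = 0
        tot = 0
        r = np.hypot(df.x_deg, df.y_deg)
        for layer in sim.LAYERS:
            mu = sim.normative_thickness(layer, r, df.baseline_age)
            z = (df[f"{layer}_thickness"] - mu) / sim.normative_thickness_sd(layer)
            ok += int((np.abs(z) < 3).sum())
            tot += len(z)
        assert ok / tot >= 0.99

    def test_full_severity_fovea_below_first_percentile(self, grid13, rng):
        cfg = sim.CohortConfig(
            n_patients=2, n_controls=1, eyes_per_patient=1,
            severity_alpha=1e6, severity_beta=1e-6, seed=9,
        )
        df = sim.synth_structure(cfg, grid13, np.random.default_rng(9))
        fovea = df[(df.x_deg == 0) & (df.y_deg == 0)]
        # control draw from the generator's own normative model (n = 500)
        age = float(fovea.baseline_age.iloc[0])
        ctrl = sim.normative_thickness("ISOS", 0.0, age) + rng.normal(
            0, sim.normative_thickness_sd("ISOS"), size=500
        )
        assert (fovea.ISOS_thickness < np.percentile(ctrl, 1)).all()

    def test_zero_progression_keeps_structure_identical_across_visits(self, grid13):
        cfg = sim.CohortConfig(
            n_patients=1, n_controls=1, eyes_per_patient=1, visits_per_eye=2,
            progression_per_year=0.0, seed=4,
        )
        df = sim.synth_structure(cfg, grid13, np.random.default_rng(4))
        v1 = df[df.visit == 1].set_index("point_id")
        v2 = df[df.visit == 2].set_index("point_id")
        for layer in sim.LAYERS:
            pd.testing.assert_series_equal(
                v1[f"{layer}_thickness"], v2[f"{layer}_thickness"], check_exact=True
            )


class TestGenerateCohorts:
    def test_row_counts_are_product_of_design(self, grid50):
        cfg = sim.CohortConfig(n_patients=3, n_controls=2, eyes_per_patient=2, seed=1)
        controls, patients = sim.generate_cohorts(cfg, grid50)
        assert len(patients) == 3 * 2 * 1 * 50
        assert len(controls) == 2 * 2 * 1 * 50

    def test_retest_shares_true_thresholds(self, cohort13):
        _, patients = cohort13
        per_test = patients.pivot_table(
            index=["eye_id", "visit", "point_id"], columns="test_index",
            values="true_sensitivity_db",
        )
        assert set(per_test.columns) == {1, 2}
        np.testing.assert_allclose(per_test[1], per_test[2])

    def test_hierarchy_keys_consistent(self, cohort13):
        controls, patients = cohort13
        for df in (controls, patients):
            eye_owner = df.groupby("eye_id").patient_id.nunique()
            assert (eye_owner == 1).all()  # eyes never shared across patients
            assert all(e.startswith(p) for e, p in zip(df.eye_id, df.patient_id))

    def test_covariates_present_and_valid(self, cohort13):
        _, patients = cohort13
        assert patients.erg_group.isin([1, 2, 3]).all()
        assert patients.onset_category.isin([0, 1, 2]).all()
        assert (patients.false_positive_responses >= 0).all()
        assert patients.sensitivity_db.between(0, 36).all()
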