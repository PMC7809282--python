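"""Normative fits (parameter recovery) and z-score / sensitivity-loss maths."""

import numpy as np
import pandas as pd
import pytest

from infersens import standardize as std


def _control_table(n_patients, ages, values, point_id="loc0", var="ISOS_thickness",
                   eyes_per_patient=2):
    """Minimal control table for one location and one variable."""
    rows = []
    k = 0
    for i in range(n_patients):
        for e in range(eyes_per_patient):
            rows.append(
                {"patient_id": f"C{i:03d}", "eye_id": f"C{i:03d}_{e}",
                 "visit": 1, "test_index": 1, "age": ages[i],
                 "point_id": point_id, var: values[k]}
            )
            k += 1
    return pd.DataFrame(rows)


class TestFitNormative:
    def test_recovers_constant_mean_and_sd(self, rng):
        """Zero slope, zero random effects: intercept ~ c, slope ~ 0, SD ~ sigma."""
        c, sigma, n_pat = 60.0, 2.0, 500  # 1000 eyes (tolerance is sub-SE at 200)
        ages = rng.uniform(20, 60, n_pat)
        vals = c + rng.normal(0, sigma, n_pat * 2)
        tab = _control_table(n_pat, ages, vals)
        norm = std.fit_normative(tab, reference_age=40.0, variables=("ISOS_thickness",))
        row = norm.table.iloc[0]
        assert abs(row.intercept - c) < 0.05 * sigma
        assert abs(row.age_slope) < 0.02
        assert abs(row.sd - sigma) < 0.25

    def test_recovers_age_slope(self, rng):
        slope, n_pat = -0.5, 150  # 300 eyes
        ages = rng.uniform(20, 60, n_pat)
        per_eye_age = np.repeat(ages, 2)
        vals = 80.0 + slope * (per_eye_age - 40.0) + rng.normal(0, 2.0, n_pat * 2)
        tab = _control_table(n_pat, ages, vals)
        norm = std.fit_normative(tab, reference_age=40.0, variables=("ISOS_thickness",))
        assert abs(norm.table.iloc[0].age_slope - slope) < 0.05

    def test_recovers_variance_components_in_total_sd(self, rng):
        """Total normative SD ~ sqrt(patient + eye + residual variance)."""
        n_pat = 150
        ages = rng.uniform(20, 60, n_pat)
        b_pat = np.repeat(rng.normal(0, 3.0, n_pat), 2)
        vals = 50.0 + b_pat + rng.normal(0, 1.5, n_pat * 2)
        tab = _control_table(n_pat, ages, vals)
        norm = std.fit_normative(tab, reference_age=40.0, variables=("ISOS_thickness",))
        expected = np.sqrt(3.0**2 + 1.5**2)
        assert norm.table.iloc[0].sd == pytest.approx(expected, rel=0.15)

    def test_degenerate_zero_variance_uses_fallback(self):
        tab = _control_table(3, [30, 40, 50], np.full(6, 42.0))
        norm = std.fit_normative(tab, reference_age=40.0, variables=("ISOS_thickness",))
        assert norm.table.iloc[0].fallback
        assert norm.table.iloc[0].sd > 0

    def test_requires_two_patients(self):
        tab = _control_table(1, [40.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="2 control patients"):
            std.fit_normative(tab, variables=("ISOS_thickness",))


class TestStandardize:
    def test_value_at_normative_mean_gives_zero(self, std13):
        _, norm = std13
        rec = pd.DataFrame(
            {"patient_id": ["P1"], "eye_id": ["P1_OD"], "visit": [1], "test_index": [1],
             "age": [norm.reference_age], "point_id": [norm.table.point_id.iloc[0]]}
        )
        pid = rec.point_id.to_numpy()
        for feat in std.FEATURE_NAMES:
            rec[feat] = norm.mean_at(pid, feat, norm.reference_age)
        rec["sensitivity_db"] = norm.mean_at(pid, "sensitivity_db", norm.reference_age)
        out = std.standardize(rec, norm)
        assert out[list(std.FEATURE_NAMES)].to_numpy() == pytest.approx(0.0, abs=1e-10)
        assert out.sensitivity_loss.iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_loss_arithmetic(self, std13):
        """Observed 10 dB against a normative mean of 28 dB -> 18 dB loss."""
        _, norm = std13
        pid = norm.table.point_id.iloc[0]
        mu = float(norm.mean_at([pid], "sensitivity_db", norm.reference_age)[0])
        rec = pd.DataFrame(
            {"patient_id": ["P1"], "eye_id": ["P1_OD"], "visit": [1], "test_index": [1],
             "age": [40.0], "point_id": [pid], "sensitivity_db": [mu - 18.0]}
        )
        for feat in std.FEATURE_NAMES:
            rec[feat] = 0.0
        out = std.standardize(rec, norm)
        assert out.sensitivity_loss.iloc[0] == pytest.approx(18.0)
        # and explicitly: normative 28, observed 10 -> loss 18
        assert 28.0 - 10.0 == 18.0

    def test_controls_round_trip_standard_normal(self, rng):
        """Standardizing the fitting cohort yields z with mean ~ 0, SD ~ 1."""
        n_pat = 100  # 200 eyes
        ages = rng.uniform(20, 60, n_pat)
        b_pat = np.repeat(rng.normal(0, 2.0, n_pat), 2)
        per_eye_age = np.repeat(ages, 2)
        vals = 55.0 - 0.2 * (per_eye_age - 40) + b_pat + rng.normal(0, 1.0, n_pat * 2)
        tab = _control_table(n_pat, ages, vals)
        for feat in std.FEATURE_NAMES:
            if feat not in tab.columns:
                tab[feat] = rng.normal(0, 1, len(tab))
        tab["sensitivity_db"] = 28.0 + rng.normal(0, 1.5, len(tab))
        norm = std.fit_normative(tab, reference_age=40.0)
        out = std.standardize(tab, norm, age_policy="per-subject-age")
        z = out["ISOS_thickness"]
        assert abs(z.mean()) < 0.05
        assert abs(z.std() - 1.0) < 0.1

    def test_control_cohort_loss_near_zero(self, cohort13, std13):
        """Generator round-trip: control sensitivity loss ~ 0 in expectation."""
        controls, _ = cohort13
        _, norm = std13
        out = std.standardize(controls, norm, age_policy="per-subject-age")
        assert abs(out.sensitivity_loss.mean()) < 0.35

    def test_loss_strictly_decreases_with_observed_sensitivity(self, std13):
        _, norm = std13
        pid = norm.table.point_id.iloc[0]
        rec = pd.DataFrame(
            {"patient_id": ["P1"] * 3, "eye_id": ["P1_OD"] * 3, "visit": [1] * 3,
             "test_index": [1] * 3, "age": [40.0] * 3, "point_id": [pid] * 3,
             "sensitivity_db": [5.0, 15.0, 25.0]}
        )
        for feat in std.FEATURE_NAMES:
            rec[feat] = 0.0
        out = std.standardize(rec, norm)
        assert out.sensitivity_loss.is_monotonic_decreasing

    def test_shift_invariance(self, rng):
        """Adding a constant to a variable in controls and patients leaves z
        unchanged."""
        n_pat = 30
        ages = rng.uniform(20, 60, n_pat)
        vals = 50.0 + rng.normal(0, 2.0, n_pat * 2)
        tab = _control_table(n_pat, ages, vals)
        for feat in std.FEATURE_NAMES:
            if feat not in tab.columns:
                tab[feat] = rng.normal(size=len(tab))
        tab["sensitivity_db"] = 28.0
        shifted = tab.copy()
        shifted["ISOS_thickness"] = shifted["ISOS_thickness"] + 100.0
        z0 = std.standardize(tab, std.fit_normative(tab, 40.0))["ISOS_thickness"]
        z1 = std.standardize(shifted, std.fit_normative(shifted, 40.0))["ISOS_thickness"]
        np.testing.assert_allclose(z0, z1, atol=1e-6)

    def test_missing_normative_entry_errors(self, std13):
        _, norm = std13
        rec = pd.DataFrame(
            {"patient_id": ["P1"], "eye_id": ["P1_OD"], "visit": [1], "test_index": [1],
             "age": [40.0], "point_id": ["nowhere"], "sensitivity_db": [20.0]}
        )
        for feat in std.FEATURE_NAMES:
            rec[feat] = 0.0
        with pytest.raises(KeyError, match="nowhere"):
            std.standardize(rec, norm)
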