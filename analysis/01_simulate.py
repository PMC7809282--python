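"""Generate the synthetic study cohorts.

Builds the 50-point perimetry grid, a bilateral patient cohort, a healthy
control cohort and a separate intra-session retest cohort, and writes them as
tidy CSVs under results/study/.
"""

from pathlib import Path

import numpy as np

from infersens import simulate as sim

OUT = Path(__file__).resolve().parents[1] / "results" / "study"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 7

grid = sim.make_grid()
grid.to_csv(OUT / "grid.csv")
print(f"grid: {grid.n_points} points; "
      f"{len(grid.meridian_ids(2))} meridian loci at 2 deg, "
      f"{len(grid.meridian_ids(4))} at 4 deg")
print(f"staircase dynamic range: {sim.StaircaseParams().db_ceiling:.0f} dB "
      f"(= {np.log10(318.5 / 0.08):.2f} log units)")

cfg = sim.CohortConfig(n_patients=16, n_controls=12, eyes_per_patient=2, seed=SEED)
controls, patients = sim.generate_cohorts(cfg, grid)
controls.to_csv(OUT / "controls.csv", index=False)
patients.to_csv(OUT / "patients.csv", index=False)
print(f"controls: {controls.patient_id.nunique()} subjects, {len(controls)} point records")
print(f"patients: {patients.patient_id.nunique()} subjects, {len(patients)} point records; "
      f"measured sensitivity spans {patients.sensitivity_db.min():.0f}-"
      f"{patients.sensitivity_db.max():.0f} dB")

rcfg = sim.CohortConfig(n_patients=12, n_controls=2, eyes_per_patient=2, retest=True,
                        seed=SEED + 100)
_, retest = sim.generate_cohorts(rcfg, grid)
retest.to_csv(OUT / "retest_patients.csv", index=False)
print(f"retest cohort: {retest.eye_id.nunique()} eyes with two test runs each")
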