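"""Shared fixtures: small synthetic cohorts generated once per session."""

import logging

import numpy as np
import pytest

from infersens import simulate as sim
from infersens import standardize as std

logging.getLogger("infersens").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def grid50():
    return sim.make_grid()


@pytest.fixture(scope="session")
def grid13():
    """Meridian-only grid (the 13 required loci)."""
    return sim.make_grid(sim.GridSpec(off_meridian={}))


@pytest.fixture(scope="session")
def cohort13(grid13):
    """Small bilateral cohort with retest sessions on the meridian grid."""
    cfg = sim.CohortConfig(n_patients=6, n_controls=6, eyes_per_patient=2, retest=True, seed=42)
    controls, patients = sim.generate_cohorts(cfg, grid13)
    return controls, patients


@pytest.fixture(scope="session")
def std13(cohort13):
    controls, patients = cohort13
    norm = std.fit_normative(controls, reference_age=float(patients.age.median()))
    return std.standardize(patients, norm), norm


@pytest.fixture(scope="session")
def cohort50(grid50):
    """Cohort on the full 50-point grid (needed for seed-locus feature-sets)."""
    cfg = sim.CohortConfig(n_patients=10, n_controls=8, eyes_per_patient=2, retest=True, seed=5)
    controls, patients = sim.generate_cohorts(cfg, grid50)
    return controls, patients


@pytest.fixture(scope="session")
def std50(cohort50):
    controls, patients = cohort50
    norm = std.fit_normative(controls, reference_age=float(patients.age.median()))
    return std.standardize(patients, norm), norm


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
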