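"""Synthetic structure-function cohorts for macular dystrophy modeling.

This module generates control and patient cohorts with the hierarchical,
structural and psychophysical properties that the downstream analysis assumes:

* a fundus-controlled perimetry stimulus grid (50 points centred on the fovea,
  dominated by a horizontal-meridian profile at 2-degree spacing),
* per-eye retinal layer architecture (FR, IR, ONL, IS&OS, RPE) following
  age-linear normative surfaces with patient/eye random intercepts, thinned in
  patients by a disease-severity field that is strongest at the fovea,
* a ground-truth structure->function map in which sensitivity loss is a
  saturating, weighted sum of layer-thickness deficits dominated by IS&OS and
  RPE thickness,
* a 4-2 staircase measurement model with a 36 dB dynamic range, psychometric
  scatter and lapse/guess rates, which quantizes thresholds onto a 2 dB
  lattice and produces realistic test-retest noise.

All randomness flows from one explicit seed per cohort; there is no global
RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import enface
from .enface import LAYERS, LatticeInfo, LayerMaps

# --------------------------------------------------------------------------
# stimulus grid
# --------------------------------------------------------------------------

#: Horizontal-meridian loci at 2-degree spacing, temporal 14 deg to nasal
#: 10 deg (negative x = temporal).  These are the seed loci for feature-set 5.
MERIDIAN_X_2DEG = tuple(range(-14, 11, 2))
#: Every-4-degree subset (no foveal point) - the seed loci for feature-set 4.
MERIDIAN_X_4DEG = (-14, -10, -6, -2, 2, 6, 10)


def _default_off_meridian() -> dict[float, tuple[float, ...]]:
    return {
        2.0: tuple(float(x) for x in MERIDIAN_X_2DEG),
        -2.0: tuple(float(x) for x in MERIDIAN_X_2DEG),
        4.0: (-12.0, -8.0, -4.0, 0.0, 4.0, 8.0),
        -4.0: (-10.0, -6.0, -2.0, 2.0, 6.0),
    }


@dataclass
class GridSpec:
    """Layout of the perimetry test pattern.

    The meridian row is mandatory; off-meridian rows are a free design choice
    (the default totals 50 points).
    """

    meridian_x: tuple[float, ...] = tuple(float(x) for x in MERIDIAN_X_2DEG)
    off_meridian: dict[float, tuple[float, ...]] = field(default_factory=_default_off_meridian)


@dataclass
class StimulusGrid:
    """Perimetry stimulus locations: ``points`` has point_id, x_deg, y_deg."""

    points: pd.DataFrame

    @property
    def n_points(self) -> int:
        return len(self.points)

    def meridian_ids(self, spacing: int = 2) -> list[str]:
        """Point ids of the horizontal-meridian loci at the given spacing."""
        wanted = MERIDIAN_X_2DEG if spacing == 2 else MERIDIAN_X_4DEG
        sel = self.points[(self.points.y_deg == 0) & self.points.x_deg.isin(wanted)]
        return list(sel.point_id)

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)


def _point_id(x: float, y: float) -> str:
    return f"x{x:+06.1f}y{y:+06.1f}"


def make_grid(spec: GridSpec | None = None) -> StimulusGrid:
    """Build the stimulus grid from a layout spec.

    Raises ``ValueError`` if the layout omits any of the 13 required
    horizontal-meridian loci (temporal 14 deg to nasal 10 deg, every 2 deg).
    """
    spec = spec or GridSpec()
    missing = [x for x in MERIDIAN_X_2DEG if x not in set(spec.meridian_x)]
    if missing:
        raise ValueError(f"grid spec omits required meridian loci at x={missing}")
    rows = [(x, 0.0) for x in spec.meridian_x]
    for y, xs in spec.off_meridian.items():
        if y == 0:
            raise ValueError("off_meridian rows must have y != 0")
        rows.extend((x, float(y)) for x in xs)
    df = pd.DataFrame(rows, columns=["x_deg", "y_deg"])
    df.insert(0, "point_id", [_point_id(x, y) for x, y in rows])
    if df.point_id.duplicated().any():
        raise ValueError("duplicate stimulus locations in grid spec")
    return StimulusGrid(points=df)


# --------------------------------------------------------------------------
# normative retinal architecture
# --------------------------------------------------------------------------

# baseline thickness profiles (micrometres) as functions of eccentricity r
# (degrees); shapes follow the usual macular topography: ONL/IS&OS peak at the
# fovea, inner retina is thinnest there.
def _base_thickness(layer: str, r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if layer == "FR":
        return 230.0 + 90.0 * (1.0 - np.exp(-((r / 2.5) ** 2))) - 2.0 * r
    if layer == "IR":
        return 20.0 + 90.0 * (1.0 - np.exp(-((r / 3.5) ** 2)))
    if layer == "ONL":
        return 55.0 + 60.0 * np.exp(-((r / 6.0) ** 2))
    if layer == "ISOS":
        return 45.0 + 20.0 * np.exp(-((r / 4.0) ** 2))
    if layer == "RPE":
        return 22.0 + 4.0 * np.exp(-((r / 5.0) ** 2))
    raise KeyError(layer)


#: Age slopes, micrometres per year (applied relative to age 40).
AGE_SLOPE_UM_PER_YR = {"FR": -0.30, "IR": -0.10, "ONL": -0.15, "ISOS": -0.05, "RPE": -0.02}

#: Between-patient / between-eye / residual (per-point) SDs, micrometres.
SD_PATIENT = {"FR": 6.0, "IR": 3.0, "ONL": 4.0, "ISOS": 3.0, "RPE": 1.5}
SD_EYE = {"FR": 2.5, "IR": 1.5, "ONL": 1.8, "ISOS": 1.4, "RPE": 0.8}
SD_RESID = {"FR": 3.0, "IR": 2.0, "ONL": 2.0, "ISOS": 1.5, "RPE": 1.0}

#: Mean reflectivity per layer (arbitrary units) and within-layer axial spread.
REFLECT_MEAN = {"FR": 0.40, "IR": 0.35, "ONL": 0.15, "ISOS": 0.55, "RPE": 0.60}
REFLECT_SPREAD = 0.25  # relative axial voxel scatter within a layer
REFLECT_SD_PATIENT = 0.020
REFLECT_SD_EYE = 0.012
REFLECT_SD_PIXEL = 0.015

#: Maximal fractional thinning at the fovea for full severity.
DISEASE_DEPTH = {"FR": 0.30, "IR": 0.05, "ONL": 0.55, "ISOS": 0.92, "RPE": 0.75}
DISEASE_ECC_SCALE_DEG = 8.0
#: SD (log scale) of the per-eye, per-layer disease-expression multiplier:
#: layer involvement varies between eyes, so layers do not thin in lockstep.
DISEASE_EXPRESSION_LOG_SD = 0.3
#: Fractional loss of mean reflectivity at full severity (outer layers).
DISEASE_REFLECT_DEPTH = {"FR": 0.10, "IR": 0.0, "ONL": 0.05, "ISOS": 0.50, "RPE": 0.30}

REFERENCE_AGE = 40.0


def normative_thickness(layer: str, r, age) -> np.ndarray:
    """Population mean thickness (um) at eccentricity ``r`` deg and ``age`` yr."""
    return _base_thickness(layer, r) + AGE_SLOPE_UM_PER_YR[layer] * (np.asarray(age, float) - REFERENCE_AGE)


def normative_thickness_sd(layer: str) -> float:
    """Total between-subject + residual SD of thickness (um)."""
    return math.sqrt(SD_PATIENT[layer] ** 2 + SD_EYE[layer] ** 2 + SD_RESID[layer] ** 2)


def normative_sensitivity(r, age=REFERENCE_AGE) -> np.ndarray:
    """Population mean light-increment sensitivity (dB) for healthy eyes."""
    r = np.asarray(r, dtype=float)
    return 28.0 - 0.18 * r - 0.05 * (np.asarray(age, float) - REFERENCE_AGE)


def disease_profile(r, severity) -> np.ndarray:
    """Spatial weight of disease effect: strongest at the fovea, fading with
    eccentricity."""
    r = np.asarray(r, dtype=float)
    return np.asarray(severity, float) * np.exp(-((r / DISEASE_ECC_SCALE_DEG) ** 2))


# --------------------------------------------------------------------------
# ground-truth structure -> function map
# --------------------------------------------------------------------------


@dataclass
class GroundTruthMap:
    """Maps layer-thickness z-scores to true sensitivity.

    ``loss = link(sum_l w_l * max(0, -z_l))`` and
    ``sensitivity = clamp(normative - loss, floor, ceiling)``.
    The default weights put IS&OS first and RPE second, ahead of all other
    layers, so that importance analyses have a known recoverable ranking.
    """

    weights: dict[str, float] = field(
        default_factory=lambda: {"ISOS": 6.0, "RPE": 4.0, "ONL": 1.2, "FR": 0.8, "IR": 0.3}
    )
    link: str = "saturating"  # or "linear"
    link_slope: float = 1.0
    link_knee_db: float = 30.0
    noise_sd_db: float = 2.0
    #: SD of the eye/session-level functional offset (dB): response criterion,
    #: fatigue and adaptation shift all thresholds of one eye's session
    #: coherently.  Invisible to imaging, visible to seed-locus test results.
    functional_offset_sd_db: float = 3.5
    db_floor: float = 0.0
    db_ceiling: float = 36.0

    def __post_init__(self):
        w = self.weights
        others = [w[l] for l in w if l not in ("ISOS", "RPE")]
        if not (w["ISOS"] >= w["RPE"] and (not others or w["RPE"] > max(others))):
            raise ValueError("weights must satisfy w_ISOS >= w_RPE > all others")

    def loss_from_deficit(self, deficit) -> np.ndarray:
        u = self.link_slope * np.asarray(deficit, dtype=float)
        if self.link == "linear":
            return u
        return self.link_knee_db * np.tanh(u / self.link_knee_db)


def true_sensitivity(z_struct: dict[str, np.ndarray] | pd.DataFrame, gt: GroundTruthMap,
                     normative_db) -> np.ndarray:
    """True threshold (dB): normative mean minus the saturating weighted sum of
    layer deficits, clamped to the instrument's dynamic range.

    ``z_struct`` maps layer name -> thickness z-score (array-like);
    ``normative_db`` is the normative mean sensitivity at the locus.
    """
    deficit = 0.0
    for layer, w in gt.weights.items():
        z = np.asarray(z_struct[layer], dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError(f"non-finite z-score for layer {layer}")
        deficit = deficit + w * np.maximum(0.0, -z)
    sens = np.asarray(normative_db, dtype=float) - gt.loss_from_deficit(deficit)
    return np.clip(sens, gt.db_floor, gt.db_ceiling)


# --------------------------------------------------------------------------
# 4-2 staircase measurement model
# --------------------------------------------------------------------------


@dataclass
class StaircaseParams:
    """Threshold staircase of a mesopic fundus-controlled perimeter.

    Dynamic range 0-36 dB (3.6 log units); 4 dB steps to the first reversal,
    2 dB steps to the second; threshold = last seen level; "not seen" at the
    maximal (brightest, 0 dB) stimulus is coded as the floor value.
    """

    db_floor: float = 0.0
    db_ceiling: float = 36.0
    initial_level: float | None = None  # default: 10 dB below ceiling
    step_coarse: float = 4.0
    step_fine: float = 2.0
    psychometric_sd_db: float = 3.0
    false_positive_rate: float = 0.01
    false_negative_rate: float = 0.01
    max_trials: int = 60

    def __post_init__(self):
        if not np.isclose(self.db_ceiling - self.db_floor, 36.0):
            raise ValueError("dynamic range must be 36 dB (3.6 log units)")
        if not (self.step_coarse == 4.0 and self.step_fine == 2.0):
            raise ValueError("step sizes are fixed at 4 and 2 dB")
        for r in (self.false_positive_rate, self.false_negative_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("lapse/guess rates must be in [0, 1]")
        if self.false_positive_rate + self.false_negative_rate > 1.0:
            raise ValueError("guess + lapse rate must not exceed 1")

    @property
    def start_level(self) -> float:
        return self.db_ceiling - 10.0 if self.initial_level is None else self.initial_level


def _p_seen(level: float, threshold: float, p: StaircaseParams) -> float:
    if p.psychometric_sd_db <= 0:
        core = 1.0 if threshold > level else (0.0 if threshold < level else 0.5)
    else:
        arg = np.clip((threshold - level) / p.psychometric_sd_db, -700, 700)
        core = 1.0 / (1.0 + math.exp(-arg))
    return p.false_positive_rate + (1.0 - p.false_positive_rate - p.false_negative_rate) * core


def run_staircase(true_threshold: float, params: StaircaseParams | None = None,
                  rng: np.random.Generator | None = None) -> float:
    """Simulate one 4-2 staircase run and return the measured sensitivity (dB).

    Yes/no responses are drawn from a logistic psychometric function with
    guess (false-positive) and lapse (false-negative) rates.  Stimuli dim by
    ``step`` after "seen" and brighten after "not seen"; the step drops from
    4 to 2 dB at the first reversal and the run ends at the second reversal.
    """
    params = params or StaircaseParams()
    rng = rng or np.random.default_rng()
    if not np.isfinite(true_threshold):
        raise ValueError("true threshold must be finite")

    level = min(max(params.start_level, params.db_floor), params.db_ceiling)
    step = params.step_coarse
    last_seen: float | None = None
    prev_response: bool | None = None
    reversals = 0

    for _ in range(params.max_trials):
        seen = bool(rng.random() < _p_seen(level, true_threshold, params))
        if seen:
            last_seen = level
        if prev_response is not None and seen != prev_response:
            reversals += 1
            if reversals == 1:
                step = params.step_fine
            else:
                break
        prev_response = seen
        if seen and level >= params.db_ceiling:
            return params.db_ceiling  # cannot present a dimmer stimulus
        if (not seen) and level <= params.db_floor:
            break  # not seen at the maximal stimulus
        level = min(max(level + (step if seen else -step), params.db_floor), params.db_ceiling)

    return last_seen if last_seen is not None else params.db_floor


# --------------------------------------------------------------------------
# cohort configuration
# --------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the clinical study design this generator emulates:
    134 patients with two eyes each, 54 controls, single baseline visit,
    patient ages centred near 37 years and controls near 41.
    """

    n_patients: int = 134
    n_controls: int = 54
    eyes_per_patient: int = 2
    visits_per_eye: int = 1
    visit_interval_yr: float = 1.5
    age_mean: float = 37.0
    age_sd: float = 15.0
    control_age_mean: float = 41.0
    control_age_sd: float = 15.0
    severity_alpha: float = 2.0
    severity_beta: float = 2.0
    progression_per_year: float = 0.04
    retest: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("n_patients", "n_controls", "eyes_per_patient", "visits_per_eye"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.eyes_per_patient not in (1, 2):
            raise ValueError("eyes_per_patient must be 1 or 2")


# --------------------------------------------------------------------------
# structural synthesis (en-face maps via synthetic volumes)
# --------------------------------------------------------------------------

_LATTICE = LatticeInfo(x0_deg=-16.0, y0_deg=-16.0, deg_per_px=0.4, nx=81, ny=81)
_AXIAL_PITCH_UM = 3.87


def _eye_layer_maps(age: float, severity: float, b_pat: dict, b_eye: dict,
                    resid_fields: dict, reflect_pat: dict, reflect_eye: dict,
                    reflect_fields: dict, dis_mult: dict,
                    rng: np.random.Generator) -> LayerMaps:
    """Render per-layer thickness + projection maps for one eye by building a
    synthetic reflectivity volume per layer and projecting it."""
    xs, ys = _LATTICE.pixel_centers()
    r = np.hypot(xs[None, :], ys[:, None])
    dis = disease_profile(r, severity)
    maps: dict[str, dict[str, np.ndarray]] = {}
    for layer in LAYERS:
        thick = (
            normative_thickness(layer, r, age) + b_pat[layer] + b_eye[layer] + resid_fields[layer]
        )
        depth = min(DISEASE_DEPTH[layer] * dis_mult[layer], 0.98)
        thick = np.maximum(thick * (1.0 - depth * dis), 0.5)
        mean_ref = (
            REFLECT_MEAN[layer] * (1.0 - DISEASE_REFLECT_DEPTH[layer] * dis)
            + reflect_pat[layer] + reflect_eye[layer] + reflect_fields[layer]
        )
        mean_ref = np.maximum(mean_ref, 0.01)

        lower = thick / _AXIAL_PITCH_UM
        upper = np.zeros_like(lower)
        nz = int(np.ceil(lower.max())) + 1
        voxels = mean_ref[..., None] * (
            1.0 + REFLECT_SPREAD * rng.standard_normal((_LATTICE.ny, _LATTICE.nx, nz))
        )
        maps[layer] = enface.project_layer(voxels, upper, lower, _AXIAL_PITCH_UM)
    return LayerMaps(lattice=_LATTICE, maps=maps)


def _draw_layer_offsets(rng, sds):
    return {layer: rng.normal(0.0, sds[layer]) for layer in LAYERS}


def synth_structure(config: CohortConfig, grid: StimulusGrid | None = None,
                    rng: np.random.Generator | None = None,
                    cohort: str = "patient") -> pd.DataFrame:
    """Generate per-point true layer thicknesses and reflectivity features.

    Returns one row per (patient, eye, visit, point) with the 20 imaging
    features sampled from rendered en-face maps, plus ``severity`` and ``age``.
    Controls are generated with ``cohort="control"`` (severity identically 0).

    Within an eye the structural random effects and the per-point residual
    field are drawn once; across visits only disease progression alters the
    structure, so a zero progression rate reproduces the baseline exactly.
    """
    grid = grid or make_grid()
    rng = rng or np.random.default_rng(config.seed)
    is_control = cohort == "control"
    n_subj = config.n_controls if is_control else config.n_patients
    prefix = "C" if is_control else "P"
    age_mu = config.control_age_mean if is_control else config.age_mean
    age_sd = config.control_age_sd if is_control else config.age_sd

    rows = []
    for i in range(n_subj):
        pid = f"{prefix}{i:04d}"
        age0 = float(np.clip(rng.normal(age_mu, age_sd), 8.0, 85.0))
        sev_pat = 0.0 if is_control else float(rng.beta(config.severity_alpha, config.severity_beta))
        b_pat = _draw_layer_offsets(rng, SD_PATIENT)
        ref_pat = {l: rng.normal(0.0, REFLECT_SD_PATIENT) for l in LAYERS}
        for e in range(config.eyes_per_patient):
            eye_id = f"{pid}_{'OD' if e == 0 else 'OS'}"
            # multiplicative between-eye asymmetry: unaffected stays unaffected
            sev_eye0 = 0.0 if is_control else float(
                np.clip(sev_pat * (1.0 + rng.normal(0, 0.15)), 0, 1)
            )
            b_eye = _draw_layer_offsets(rng, SD_EYE)
            ref_eye = {l: rng.normal(0.0, REFLECT_SD_EYE) for l in LAYERS}
            shape = (_LATTICE.ny, _LATTICE.nx)
            resid_fields = {l: rng.normal(0.0, SD_RESID[l], size=shape) for l in LAYERS}
            reflect_fields = {l: rng.normal(0.0, REFLECT_SD_PIXEL, size=shape) for l in LAYERS}
            dis_mult = {
                l: float(np.exp(rng.normal(0.0, DISEASE_EXPRESSION_LOG_SD))) for l in LAYERS
            }
            vox_seed = int(rng.integers(2**31))
            for v in range(config.visits_per_eye):
                dt = v * config.visit_interval_yr
                sev = 0.0 if is_control else float(
                    np.clip(sev_eye0 + config.progression_per_year * dt, 0, 1)
                )
                maps = _eye_layer_maps(
                    age0, sev, b_pat, b_eye, resid_fields, ref_pat, ref_eye,
                    reflect_fields, dis_mult, np.random.default_rng(vox_seed),
                )
                feats = enface.sample_at_stimuli(maps, grid)
                block = grid.points.merge(feats.reset_index(), on="point_id")
                block.insert(0, "patient_id", pid)
                block.insert(1, "eye_id", eye_id)
                block.insert(2, "visit", v + 1)
                block.insert(3, "age", age0 + dt)
                block.insert(4, "baseline_age", age0)
                block.insert(5, "severity", sev)
                rows.append(block)
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# full cohort generation
# --------------------------------------------------------------------------

RELIABILITY_COLS = ("false_positive_responses", "mean_reaction_time_ms")
COVARIATE_COLS = ("fixation_stability", "bcva_logmar", "erg_group", "onset_category")

#: How strongly the structure-independent components of fixation instability
#: (log10 deg^2) and BCVA (logMAR) couple into the session-level functional
#: offset (dB): unstable fixation and poor acuity depress measured thresholds
#: beyond what retinal structure explains.
FIXATION_OFFSET_DB = -6.0
BCVA_OFFSET_DB = -6.5
FIXATION_NOISE_SD = 0.25
BCVA_NOISE_SD = 0.15


def _structural_z_truth(df: pd.DataFrame) -> pd.DataFrame:
    """Layer-thickness z-scores against the generator's own population model,
    evaluated at each eye's baseline age."""
    r = np.hypot(df.x_deg.to_numpy(), df.y_deg.to_numpy())
    z = {}
    for layer in LAYERS:
        mu = normative_thickness(layer, r, df.baseline_age.to_numpy())
        z[layer] = (df[f"{layer}_thickness"].to_numpy() - mu) / normative_thickness_sd(layer)
    return pd.DataFrame(z, index=df.index)


def generate_cohorts(
    config: CohortConfig,
    grid: StimulusGrid | None = None,
    gt: GroundTruthMap | None = None,
    staircase: StaircaseParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (controls, patients) tables of point records.

    Each row is one stimulus location at one test run: hierarchy keys
    (patient, eye, visit, test_index), the 20 imaging features, per-test
    reliability indices, patient covariates, the true threshold and the
    staircase-measured ``sensitivity_db``.  With ``config.retest`` each
    (eye, visit) carries two test instances sharing true thresholds.
    """
    grid = grid or make_grid()
    gt = gt or GroundTruthMap()
    staircase = staircase or StaircaseParams(
        db_floor=gt.db_floor, db_ceiling=gt.db_ceiling
    )
    out = []
    for cohort, sub_seed in (("control", 1), ("patient", 2)):
        rng = np.random.default_rng((config.seed, sub_seed))
        struct = synth_structure(config, grid, rng, cohort=cohort)
        z = _structural_z_truth(struct)
        r = np.hypot(struct.x_deg.to_numpy(), struct.y_deg.to_numpy())
        norm_db = normative_sensitivity(r, struct.baseline_age.to_numpy())
        clean = true_sensitivity({l: z[l] for l in LAYERS}, gt, norm_db)

        # patient-level covariates
        pat_sev = struct.groupby("patient_id").severity.mean()
        erg, onset = {}, {}
        for pid, s in pat_sev.items():
            lat = s + rng.normal(0, 0.15)
            erg[pid] = 1 + int(lat > 0.55) + int(lat > 0.80)
            lat2 = s + rng.normal(0, 0.20)
            onset[pid] = 0 if lat2 < 0.35 else (1 if lat2 < 0.65 else 2)

        eye_visit = struct.groupby(["eye_id", "visit"], sort=False)
        n_tests = 2 if config.retest else 1
        for (eye_id, visit), block in eye_visit:
            sev = float(block.severity.iloc[0])
            bio = rng.normal(0.0, gt.noise_sd_db, size=len(block))
            fix_noise = rng.normal(0, FIXATION_NOISE_SD)
            bcva_noise = rng.normal(0, BCVA_NOISE_SD)
            # functional offset: a covariate-predictable part plus a purely
            # latent part, with total SD = gt.functional_offset_sd_db
            pred_var = (FIXATION_OFFSET_DB * FIXATION_NOISE_SD) ** 2 + (
                BCVA_OFFSET_DB * BCVA_NOISE_SD
            ) ** 2
            pure_sd = float(np.sqrt(max(gt.functional_offset_sd_db**2 - pred_var, 0.0)))
            offset = (
                FIXATION_OFFSET_DB * fix_noise
                + BCVA_OFFSET_DB * bcva_noise
                + rng.normal(0.0, pure_sd)
            )
            truth = np.clip(clean[block.index] + bio + offset, gt.db_floor, gt.db_ceiling)
            bcva = float(np.clip(0.05 + 1.1 * sev + bcva_noise, -0.1, 1.6))
            fix = 0.6 + 0.9 * sev + fix_noise
            pid = block.patient_id.iloc[0]
            for t in range(1, n_tests + 1):
                meas = np.array([run_staircase(th, staircase, rng) for th in truth])
                fp = int(rng.binomial(10, min(0.02 + 0.06 * sev, 0.9)))
                rt = float(rng.normal(520 + 120 * sev, 40))
                rec = block.copy()
                rec["cohort"] = cohort
                rec["test_index"] = t
                rec["true_sensitivity_db"] = truth
                rec["sensitivity_db"] = meas
                rec["false_positive_responses"] = fp
                rec["mean_reaction_time_ms"] = rt
                rec["fixation_stability"] = fix
                rec["bcva_logmar"] = bcva
                rec["erg_group"] = erg[pid]
                rec["onset_category"] = onset[pid]
                out.append(rec)
    frames = pd.concat(out, ignore_index=True)
    controls = frames[frames.patient_id.str.startswith("C")].reset_index(drop=True)
    patients = frames[frames.patient_id.str.startswith("P")].reset_index(drop=True)
    return controls, patients
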