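"""Normative standardization of structure-function data.

For every stimulus location and every variable (the 20 imaging features and
measured sensitivity), a normative model is fitted on the control cohort:
a linear age fixed effect with random intercepts for eye nested in patient
(mixed linear model).  The normative SD is the total (marginal) SD,
sqrt(var_patient + var_eye + var_residual), so that z-scores express deviation
relative to between-subject normal variability.

Patient data are then transformed to

* structural z-scores  z = (x - x_normative) / SD_normative, and
* sensitivity loss     loss = normative mean sensitivity - observed (dB),
  positive = worse than normal,

with the normative mean evaluated either at one fixed reference age (the
patient cohort's median age; default) or at each subject's own age.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .enface import FEATURE_NAMES

log = logging.getLogger(__name__)

#: All standardized variables: 20 imaging features plus measured sensitivity.
VARIABLES = FEATURE_NAMES + ("sensitivity_db",)


@dataclass
class NormativeTable:
    """Per-(location, variable) normative model parameters.

    ``table`` columns: point_id, variable, intercept (normative mean at
    ``reference_age``), age_slope (units/yr), sd (> 0), fallback (bool: OLS
    fallback used).
    """

    table: pd.DataFrame
    reference_age: float

    def mean_at(self, point_ids, variable: str, age) -> np.ndarray:
        sub = self._lookup(point_ids, variable)
        return sub["intercept"].to_numpy() + sub["age_slope"].to_numpy() * (
            np.asarray(age, dtype=float) - self.reference_age
        )

    def sd_of(self, point_ids, variable: str) -> np.ndarray:
        return self._lookup(point_ids, variable)["sd"].to_numpy()

    def _lookup(self, point_ids, variable: str) -> pd.DataFrame:
        sub = self.table[self.table.variable == variable].set_index("point_id")
        missing = sorted(set(point_ids) - set(sub.index))
        if missing:
            raise KeyError(f"no normative entry for variable {variable!r} at locations {missing}")
        return sub.loc[list(point_ids)]

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["reference_age"] = self.reference_age
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "NormativeTable":
        df = pd.read_csv(path)
        ref = float(df["reference_age"].iloc[0])
        return cls(table=df.drop(columns=["reference_age"]), reference_age=ref)


def _fit_one(sub: pd.DataFrame, variable: str, reference_age: float) -> dict:
    """Mixed model for one (location, variable): value ~ age, random intercepts
    for eye nested in patient.  Falls back to OLS + pooled SD when the mixed
    fit is singular or fails."""
    y = sub[variable].to_numpy(dtype=float)
    age_c = sub["age"].to_numpy(dtype=float) - reference_age
    multi_eye = sub.groupby("patient_id")["eye_id"].nunique().max() > 1
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = pd.DataFrame(
                {"y": y, "age_c": age_c, "patient_id": sub.patient_id.values,
                 "eye_id": sub.eye_id.values}
            )
            vc = {"eye": "0 + C(eye_id)"} if multi_eye else None
            model = smf.mixedlm(
                "y ~ age_c", df, groups=df.patient_id, re_formula="1", vc_formula=vc
            )
            res = model.fit(reml=True, method="lbfgs")
        var_patient = float(np.asarray(res.cov_re).squeeze())
        var_eye = float(res.vcomp[0]) if vc else 0.0
        var_resid = float(res.scale)
        sd = float(np.sqrt(var_patient + var_eye + var_resid))
        params = res.fe_params
        if not np.isfinite(sd) or sd <= 0 or not np.all(np.isfinite(params)):
            raise ValueError("singular mixed fit")
        return {
            "intercept": float(params["Intercept"]),
            "age_slope": float(params["age_c"]),
            "sd": sd,
            "fallback": False,
        }
    except Exception as exc:  # singular fit, convergence failure, ...
        log.warning(
            "normative mixed fit failed for %s at a location (%s); "
            "falling back to OLS with pooled SD", variable, exc,
        )
        X = sm.add_constant(age_c)
        ols = sm.OLS(y, X).fit()
        resid_sd = float(np.std(y - ols.fittedvalues, ddof=min(2, len(y) - 1)))
        if resid_sd <= 0:
            resid_sd = max(abs(np.mean(y)) * 1e-6, 1e-8)
            log.warning("degenerate (zero-variance) normative data for %s", variable)
        return {
            "intercept": float(ols.params[0]),
            "age_slope": float(ols.params[1]) if len(ols.params) > 1 else 0.0,
            "sd": resid_sd,
            "fallback": True,
        }


def fit_normative(
    controls: pd.DataFrame,
    reference_age: float | None = None,
    variables: tuple[str, ...] = VARIABLES,
) -> NormativeTable:
    """Fit per-location, per-variable normative models on the control cohort.

    Parameters
    ----------
    controls
        Point-record table of healthy eyes (one row per stimulus location per
        test run).
    reference_age
        Age at which normative means are anchored; by convention the *patient*
        cohort's median age.  Defaults to the median age in ``controls``.
    """
    if controls.patient_id.nunique() < 2:
        raise ValueError("need at least 2 control patients for normative fits")
    if reference_age is None:
        reference_age = float(controls.age.median())
    rows = []
    for pid, sub in controls.groupby("point_id", sort=False):
        for variable in variables:
            est = _fit_one(sub, variable, reference_age)
            est.update({"point_id": pid, "variable": variable})
            rows.append(est)
    table = pd.DataFrame(rows)[["point_id", "variable", "intercept", "age_slope", "sd", "fallback"]]
    return NormativeTable(table=table, reference_age=float(reference_age))


def standardize(
    records: pd.DataFrame,
    norm: NormativeTable,
    age_policy: str = "reference-age",
) -> pd.DataFrame:
    """Transform point records to structural z-scores and sensitivity loss.

    The 20 imaging feature columns are replaced by their z-scores; a
    ``sensitivity_loss`` column (dB, positive = worse than normal) is added.
    ``age_policy`` is ``"reference-age"`` (normative means evaluated at the
    normative table's fixed reference age; default) or ``"per-subject-age"``.
    """
    if age_policy not in ("reference-age", "per-subject-age"):
        raise ValueError(f"unknown age_policy {age_policy!r}")
    out = records.copy()
    age = (
        np.full(len(records), norm.reference_age)
        if age_policy == "reference-age"
        else records.age.to_numpy(dtype=float)
    )
    pids = records.point_id.to_numpy()
    for feat in FEATURE_NAMES:
        mu = norm.mean_at(pids, feat, age)
        sd = norm.sd_of(pids, feat)
        out[feat] = (records[feat].to_numpy(dtype=float) - mu) / sd
    sens_mu = norm.mean_at(pids, "sensitivity_db", age)
    out["sensitivity_loss"] = sens_mu - records["sensitivity_db"].to_numpy(dtype=float)
    return out
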