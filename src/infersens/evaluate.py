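"""Hierarchy-aware accuracy estimation and test-retest agreement.

Per-point errors from repeated perimetry data are not independent: points sit
within visits, visits within eyes, eyes within patients.  Accuracy metrics
(MAE, RMSE) are therefore estimated with an intercept-only linear mixed model
on the per-point absolute (or squared) errors, with nested random intercepts
(visit in eye in patient); the fixed intercept is the metric estimate and its
Wald interval the 95% CI.  Estimates are computed per model seed and then
averaged; the combined CI adds within-seed and between-seed variance.

Bland-Altman agreement (mean difference and 95% limits of agreement) is
computed the same way: the mean difference is the mixed-model intercept and
the limits use the total SD (variance components + residual).

Stimulus locations are stratified by ETDRS subfield; ring diameters of
1/3/6 mm are converted to degrees with 291 um/degree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .enface import MICRON_PER_DEGREE

log = logging.getLogger(__name__)

#: ETDRS ring radii (1/3/6 mm diameters) in degrees of visual angle.
CENTRAL_RADIUS_DEG = 500.0 / MICRON_PER_DEGREE  # 1.72
INNER_RADIUS_DEG = 1500.0 / MICRON_PER_DEGREE  # 5.15
OUTER_RADIUS_DEG = 3000.0 / MICRON_PER_DEGREE  # 10.31

SUBFIELDS = (
    "central", "inner nasal", "inner temporal", "outer nasal", "outer temporal",
    "nasal periphery", "temporal periphery",
)


def subfield_of(x_deg: float, y_deg: float) -> str:
    """ETDRS subfield of a stimulus location (negative x = temporal).

    Nasal/temporal halves split at x = 0 (x >= 0 counts as nasal); points
    beyond the outer ring belong to the nasal/temporal periphery.
    """
    r = float(np.hypot(x_deg, y_deg))
    side = "nasal" if x_deg >= 0 else "temporal"
    if r < CENTRAL_RADIUS_DEG:
        return "central"
    if r < INNER_RADIUS_DEG:
        return f"inner {side}"
    if r < OUTER_RADIUS_DEG:
        return f"outer {side}"
    return f"{side} periphery"


@dataclass
class AccuracyEstimate:
    metric: str  # "MAE" or "RMSE"
    estimate: float
    ci_low: float
    ci_high: float
    stratum: str = "overall"
    n: int = 0


@dataclass
class BlandAltman:
    mean_diff: float
    mean_diff_ci: tuple[float, float]
    loa_low: float
    loa_low_ci: tuple[float, float]
    loa_high: float
    loa_high_ci: tuple[float, float]
    mode: str = "retest"


def _hier_intercept(values: np.ndarray, keys: pd.DataFrame) -> tuple[float, float, dict]:
    """Intercept and SE of an intercept-only mixed model with nested random
    intercepts patient > eye > visit; returns (intercept, se, varcomps).

    Grouping levels without replication are dropped; if the mixed fit fails
    entirely, falls back to the grand mean with patient-cluster-robust SE.
    """
    df = pd.DataFrame(
        {
            "v": np.asarray(values, dtype=float),
            "patient_id": keys.patient_id.to_numpy(),
            "eye_id": keys.eye_id.to_numpy(),
            "visit_key": keys.eye_id.astype(str).to_numpy()
            + "/" + keys.visit.astype(str).to_numpy(),
        }
    )
    levels = []
    if df.groupby("patient_id").eye_id.nunique().max() > 1:
        levels.append(("eye", "0 + C(eye_id)"))
    if df.groupby("eye_id").visit_key.nunique().max() > 1:
        levels.append(("visit", "0 + C(visit_key)"))
    if df.patient_id.nunique() >= 2:
        for drop in range(len(levels) + 1):
            vc = dict(levels[: len(levels) - drop]) or None
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = smf.mixedlm(
                        "v ~ 1", df, groups=df.patient_id, re_formula="1", vc_formula=vc
                    ).fit(reml=True, method="lbfgs")
                inter = float(res.fe_params["Intercept"])
                se = float(res.bse_fe["Intercept"])
                # plausibility: the intercept must sit within the span of the
                # patient-level means and its SE must not dwarf the data scale
                pm = df.groupby("patient_id").v.mean()
                span = float(pm.max() - pm.min()) + float(df.v.std(ddof=0)) + 1e-9
                plausible = (
                    pm.min() - span <= inter <= pm.max() + span and 0 < se <= 10 * span
                )
                if np.isfinite(inter) and np.isfinite(se) and plausible:
                    vcomp = {"patient": float(np.asarray(res.cov_re).squeeze()), "resid": float(res.scale)}
                    for name, val in zip([n for n, _ in levels[: len(levels) - drop]], res.vcomp):
                        vcomp[name] = float(val)
                    return inter, se, vcomp
            except Exception as exc:
                log.warning("mixed fit failed (%s); dropping a grouping level", exc)
    # fallback: grand mean, patient-cluster-robust SE
    import statsmodels.api as sm

    ols = sm.OLS(df.v.to_numpy(), np.ones((len(df), 1))).fit(
        cov_type="cluster", cov_kwds={"groups": df.patient_id}
    )
    return float(ols.params[0]), float(ols.bse[0]), {"resid": float(np.var(df.v, ddof=1))}


def _combine_seeds(ests: list[float], ses: list[float]) -> tuple[float, float]:
    est = float(np.mean(ests))
    within = float(np.mean(np.square(ses)))
    between = float(np.var(ests, ddof=1)) if len(ests) > 1 else 0.0
    return est, float(np.sqrt(within + between * (1 + 1 / len(ests))))


def hierarchical_metric(pred_frame: pd.DataFrame, metric: str = "MAE",
                        stratum: str = "overall") -> AccuracyEstimate:
    """Hierarchy-aware MAE or RMSE with 95% CI, averaged over seeds.

    ``pred_frame`` needs columns observed, predicted, seed, patient_id,
    eye_id, visit.
    """
    if metric not in ("MAE", "RMSE"):
        raise ValueError(f"unknown metric {metric!r}")
    if pred_frame.patient_id.nunique() < 2:
        raise ValueError("need >= 2 patients for hierarchical error estimation")
    ests, ses = [], []
    for _, g in pred_frame.groupby("seed"):
        err = np.abs(g.observed.to_numpy() - g.predicted.to_numpy())
        if metric == "RMSE":
            inter, se, _ = _hier_intercept(err**2, g)
            inter = max(inter, 1e-12)
            ests.append(float(np.sqrt(inter)))
            ses.append(se / (2.0 * np.sqrt(inter)))  # delta method
        else:
            inter, se, _ = _hier_intercept(err, g)
            ests.append(inter)
            ses.append(se)
    est, se = _combine_seeds(ests, ses)
    return AccuracyEstimate(
        metric=metric, estimate=est, ci_low=est - 1.96 * se, ci_high=est + 1.96 * se,
        stratum=stratum, n=len(pred_frame),
    )


def subfield_table(pred_frame: pd.DataFrame, metric: str = "MAE") -> pd.DataFrame:
    """Accuracy per ETDRS subfield (plus 'overall'), one row per stratum."""
    frame = pred_frame.copy()
    frame["subfield"] = [subfield_of(x, y) for x, y in zip(frame.x_deg, frame.y_deg)]
    rows = []
    strata = [("overall", frame)] + [
        (sf, frame[frame.subfield == sf]) for sf in SUBFIELDS if (frame.subfield == sf).any()
    ]
    for name, g in strata:
        est = hierarchical_metric(g, metric=metric, stratum=name)
        rows.append(
            {"stratum": name, "metric": metric, "estimate": est.estimate,
             "ci_low": est.ci_low, "ci_high": est.ci_high, "n": est.n}
        )
    return pd.DataFrame(rows)


def make_retest_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Pair the two test instances of each (eye, visit, point).

    Returns keys + value1/value2 (sensitivity loss if present, else dB).
    Errors if any row lacks its partner.
    """
    val = "sensitivity_loss" if "sensitivity_loss" in records.columns else "sensitivity_db"
    idx = ["patient_id", "eye_id", "visit", "point_id", "x_deg", "y_deg"]
    wide = records.pivot_table(index=idx, columns="test_index", values=val, aggfunc="first")
    if not {1, 2} <= set(wide.columns):
        raise ValueError("retest pairing requires test_index values 1 and 2")
    unpaired = wide[wide[1].isna() | wide[2].isna()]
    if len(unpaired):
        raise ValueError(f"unpaired retest rows: {list(unpaired.index[:5])}")
    out = wide.reset_index().rename(columns={1: "value1", 2: "value2"})
    return out


def bland_altman(pairs: pd.DataFrame, mode: str = "retest") -> BlandAltman:
    """Bland-Altman mean difference and 95% limits of agreement under
    clustering.

    ``pairs`` needs patient_id, eye_id, visit, value1, value2.  The mean
    difference is the nested-mixed-model intercept; LoA = mean +- 1.96 x total
    SD (variance components + residual).  LoA CIs use a MOVER-style
    approximation with the cluster-based SE of mean and SD.
    """
    need = {"patient_id", "eye_id", "visit", "value1", "value2"}
    if not need <= set(pairs.columns):
        raise ValueError(f"pairs table missing columns {sorted(need - set(pairs.columns))}")
    diff = pairs.value1.to_numpy(dtype=float) - pairs.value2.to_numpy(dtype=float)
    inter, se, vcomp = _hier_intercept(diff, pairs)
    total_var = float(sum(vcomp.values()))
    sd_tot = float(np.sqrt(total_var))
    n_cluster = pairs.eye_id.nunique()
    se_sd = sd_tot / np.sqrt(2.0 * max(n_cluster - 1, 1))
    se_loa = float(np.sqrt(se**2 + (1.96 * se_sd) ** 2))
    lo, hi = inter - 1.96 * sd_tot, inter + 1.96 * sd_tot
    return BlandAltman(
        mean_diff=inter,
        mean_diff_ci=(inter - 1.96 * se, inter + 1.96 * se),
        loa_low=lo, loa_low_ci=(lo - 1.96 * se_loa, lo + 1.96 * se_loa),
        loa_high=hi, loa_high_ci=(hi - 1.96 * se_loa, hi + 1.96 * se_loa),
        mode=mode,
    )


def compare_model_vs_retest(pred_frame: pd.DataFrame, pairs: pd.DataFrame) -> dict:
    """MAE and RMSE of model predictions vs of test-retest differences on the
    same eyes, with CIs and a flag for which source is smaller per metric.

    Retest "errors" are |test1 - test2| per point; prediction errors are
    |predicted - observed| restricted to the eyes present in ``pairs``.
    """
    eyes = set(pairs.eye_id)
    sub = pred_frame[pred_frame.eye_id.isin(eyes)]
    if sub.empty:
        raise ValueError("prediction set and retest pairs share no eyes")
    report = {}
    retest = pairs.assign(
        observed=pairs.value1, predicted=pairs.value2, seed=0
    )
    for metric in ("MAE", "RMSE"):
        m_model = hierarchical_metric(sub, metric=metric, stratum="prediction")
        m_retest = hierarchical_metric(retest, metric=metric, stratum="retest")
        report[metric] = {
            "prediction": m_model, "retest": m_retest,
            "smaller": "prediction" if m_model.estimate < m_retest.estimate else "retest",
        }
    return report
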