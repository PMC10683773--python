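"""Goodness of fit, model comparison, dynamic ranges, edge flags, structure-function.

Assessment machinery for the fitted summation template: R^2 (percent of
variance explained) and RMSE by severity group with subject-level bootstrap
confidence intervals, paired comparison of the two competing fits
(horizontal vs vertical template shift), dynamic range of density estimates
as the width of the 1st-99th percentile interval, flagging of locations
whose largest-stimulus sensitivity exceeds the upper prediction-error limit
(an edge-of-scotoma signature), and RMSEs of structure-based predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .summation_template import TemplateParameters, template_sensitivity

__all__ = [
    "GoodnessOfFit",
    "goodness_of_fit",
    "bootstrap_compare",
    "dynamic_range",
    "dynamic_range_ratio",
    "EdgeFlags",
    "flag_edge_locations",
    "structure_function_eval",
    "test_retest_noise",
    "error_by_sensitivity_bin",
]

#: cohort label excluded from fit statistics (used for calibration instead)
CALIBRATION_COHORT = "young"


def _apply_censoring_mode(observed, predicted, censored, mode: str, limit: float):
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    keep = np.ones(obs.size, dtype=bool)
    if mode == "recorded":
        # compare on the device's recorded scale: what would be recorded as
        # the censoring limit is clamped there on both sides
        pred = np.maximum(pred, limit)
    elif mode == "exclude":
        if censored is not None:
            keep = ~np.asarray(censored).astype(bool)
    elif mode != "raw":
        raise ValueError("censored_mode must be 'recorded', 'exclude' or 'raw'")
    return obs[keep], pred[keep], keep


def _r2_rmse(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0.0:
        return np.nan, rmse
    r2 = 100.0 * (1.0 - float(resid @ resid) / sstot)
    return r2, rmse


@dataclass
class GoodnessOfFit:
    r2_overall: float            # percent of variance explained
    rmse_overall: float          # dB
    by_group: pd.DataFrame       # group, n, r2, rmse
    n: int
    r2_defined: bool = True
    censored_mode: str = "recorded"


def goodness_of_fit(
    observed,
    predicted,
    groups,
    *,
    censored=None,
    exclude_calibration_cohort: bool = True,
    calibration_label: str = CALIBRATION_COHORT,
    censored_mode: str = "recorded",
    censor_limit: float = 0.0,
) -> GoodnessOfFit:
    """R^2 (%) and RMSE (dB), overall and per severity group.

    Rows from the calibration cohort are excluded from the statistics when
    ``exclude_calibration_cohort`` is set (they are used to fit the
    template, not to judge it).  Censored rows enter at the recorded value
    by default, with predictions clamped at the censoring limit; modes
    ``'exclude'`` and ``'raw'`` are available.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    grp = np.asarray(groups)
    if not (obs.size == pred.size == grp.size):
        raise ValueError("observed, predicted and groups must be aligned")
    cen = None if censored is None else np.asarray(censored)
    include = np.ones(obs.size, dtype=bool)
    if exclude_calibration_cohort:
        include &= grp != calibration_label
    obs, pred, grp = obs[include], pred[include], grp[include]
    if cen is not None:
        cen = cen[include]

    o, p, keep = _apply_censoring_mode(obs, pred, cen, censored_mode, censor_limit)
    g = grp[keep]
    r2, rmse = _r2_rmse(o, p)
    if np.isnan(r2):
        warnings.warn("observed values have zero variance; R^2 undefined")
    rows = []
    for name in pd.unique(g):
        m = g == name
        gr2, grmse = _r2_rmse(o[m], p[m])
        rows.append({"group": name, "n": int(m.sum()), "r2": gr2, "rmse": grmse})
    return GoodnessOfFit(
        r2_overall=r2,
        rmse_overall=rmse,
        by_group=pd.DataFrame(rows),
        n=int(o.size),
        r2_defined=not np.isnan(r2),
        censored_mode=censored_mode,
    )


# ---------------------------------------------------------------------------
# Paired bootstrap comparison (subject as the resampling unit)
# ---------------------------------------------------------------------------

def bootstrap_compare(
    errors_h1,
    errors_h2,
    subject_ids,
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Paired subject-level bootstrap of RMSE under two competing fits.

    Resamples subjects with replacement (both error vectors together, so the
    comparison stays paired), and returns percentile CIs for each RMSE, for
    the percent RMSE reduction of model 1 vs model 2, and a two-sided
    bootstrap p-value for the RMSE difference.
    """
    e1 = np.asarray(errors_h1, dtype=float)
    e2 = np.asarray(errors_h2, dtype=float)
    subj = np.asarray(subject_ids)
    if not (e1.size == e2.size == subj.size):
        raise ValueError("error vectors and subject ids must be aligned")
    if B < 2:
        raise ValueError("B must be >= 2")
    uniq = pd.unique(subj)
    if uniq.size < 2:
        raise ValueError("paired bootstrap needs >= 2 subjects")

    def rmse(v):
        return float(np.sqrt(np.mean(v**2)))

    idx_by_subj = {s: np.flatnonzero(subj == s) for s in uniq}
    r1_pt, r2_pt = rmse(e1), rmse(e2)
    rng = np.random.default_rng(seed)
    r1_b = np.empty(B)
    r2_b = np.empty(B)
    for b in range(B):
        chosen = rng.choice(uniq, size=uniq.size, replace=True)
        idx = np.concatenate([idx_by_subj[s] for s in chosen])
        r1_b[b] = rmse(e1[idx])
        r2_b[b] = rmse(e2[idx])
    diff = r2_b - r1_b
    if np.allclose(e1, e2):
        p = 1.0
    else:
        p = 2.0 * min(float(np.mean(diff <= 0)), float(np.mean(diff >= 0)))
        p = min(1.0, max(p, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        imp_b = 100.0 * (1.0 - r1_b / r2_b)
    return {
        "rmse_h1": r1_pt,
        "rmse_h1_ci": tuple(np.percentile(r1_b, [2.5, 97.5])),
        "rmse_h2": r2_pt,
        "rmse_h2_ci": tuple(np.percentile(r2_b, [2.5, 97.5])),
        "improvement_pct": 100.0 * (1.0 - r1_pt / r2_pt) if r2_pt > 0 else 0.0,
        "improvement_pct_ci": tuple(np.percentile(imp_b, [2.5, 97.5])),
        "p_value": p,
        "B": B,
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# Dynamic range
# ---------------------------------------------------------------------------

def dynamic_range(values) -> float:
    """Width of the 1st-99th percentile interval of dB estimates."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("dynamic range needs >= 2 finite values")
    q01, q99 = np.percentile(v, [1.0, 99.0])
    return float(q99 - q01)


def dynamic_range_ratio(
    structural_db: pd.DataFrame,
    functional_db: pd.DataFrame,
    *,
    value_cols: tuple[str, str] = ("structural_db", "functional_db"),
    eye_col: str = "eye_id",
) -> pd.DataFrame:
    """Per-eye structural and functional dynamic ranges and their ratio.

    Expects one merged frame per estimate or two frames sharing ``eye_col``;
    here: two aligned frames with columns ``eye_col`` and the value column.
    """
    s_col, f_col = value_cols
    merged = structural_db.merge(
        functional_db, on=[eye_col, "x_deg", "y_deg"], how="inner"
    )
    rows = []
    for eye, g in merged.groupby(eye_col):
        dr_s = dynamic_range(g[s_col])
        dr_f = dynamic_range(g[f_col])
        rows.append(
            {
                eye_col: eye,
                "dr_structural": dr_s,
                "dr_functional": dr_f,
                "ratio": dr_s / dr_f if dr_f > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Edge-of-scotoma flags
# ---------------------------------------------------------------------------

@dataclass
class EdgeFlags:
    threshold_db: float          # 97.5th percentile of the G-V prediction error
    flags: np.ndarray            # per-location boolean
    errors: np.ndarray
    underpowered: bool


def flag_edge_locations(observed_gv, predicted_gv) -> EdgeFlags:
    """Flag locations whose largest-stimulus sensitivity exceeds the upper
    prediction-error limit (97.5th percentile of observed - predicted)."""
    obs = np.asarray(observed_gv, dtype=float)
    pred = np.asarray(predicted_gv, dtype=float)
    if obs.size != pred.size or obs.size == 0:
        raise ValueError("need aligned, non-empty G-V observations/predictions")
    err = obs - pred
    threshold = float(np.percentile(err, 97.5))
    underpowered = obs.size < 40
    if underpowered:
        warnings.warn(
            f"only {obs.size} G-V rows; the 97.5% limit is underpowered"
        )
    return EdgeFlags(
        threshold_db=threshold,
        flags=err > threshold,
        errors=err,
        underpowered=underpowered,
    )


# ---------------------------------------------------------------------------
# Structure-function
# ---------------------------------------------------------------------------

def structure_function_eval(
    observations: pd.DataFrame,
    structural_densities: pd.DataFrame,
    template: TemplateParameters,
    functional_densities: pd.DataFrame | None = None,
    *,
    gi_threshold_db: float = 10.0,
    density_col: str = "poff_density_per_deg2",
) -> dict:
    """RMSE of structure-based predictions, mirroring the functional analysis.

    (a) sensitivities predicted by feeding structural P-OFF densities through
    the template vs observed; (b) the same restricted to locations whose
    mean recorded G-I sensitivity is >= ``gi_threshold_db``; (c) structural
    vs functional density estimates in dB.

    ``observations`` needs per-row ``area_deg2``, ``duration_ms`` and
    ``convergence``; density tables need ``eye_id, x_deg, y_deg`` and a
    density (cells/deg^2) or dB column.
    """
    key = ["eye_id", "x_deg", "y_deg"]
    df = observations.merge(
        structural_densities[key + [density_col]].rename(
            columns={density_col: "_sd"}
        ),
        on=key,
        how="left",
    )
    if df["_sd"].isna().any():
        raise ValueError("structural densities missing for some observed locations")
    val = df["area_deg2"] * df["duration_ms"] * df["_sd"] * df["convergence"]
    with np.errstate(divide="ignore"):
        u = 10.0 * np.log10(val.to_numpy())
    pred = template_sensitivity(u, template)
    obs = df["sensitivity_db"].to_numpy(dtype=float)
    err = obs - np.maximum(pred, 0.0)
    out = {"rmse_all_db": float(np.sqrt(np.mean(err**2)))}

    gi = df.loc[df["stimulus"] == "GI"]
    if gi.empty:
        warnings.warn("no G-I rows; the >= 10 dB subset analysis is skipped")
        out["rmse_gi_subset_db"] = np.nan
    else:
        gi_mean = gi.groupby(key)["sensitivity_db"].mean()
        good = set(gi_mean.index[gi_mean >= gi_threshold_db])
        mask = pd.MultiIndex.from_frame(df[key]).isin(good)
        if mask.any():
            out["rmse_gi_subset_db"] = float(np.sqrt(np.mean(err[mask] ** 2)))
        else:
            out["rmse_gi_subset_db"] = np.nan

    if functional_densities is not None:
        fcol = (
            density_col
            if density_col in functional_densities.columns
            else "density_db_mean"
        )
        m = (
            structural_densities[key + [density_col]]
            .rename(columns={density_col: "_s"})
            .merge(
                functional_densities[key + [fcol]].rename(columns={fcol: "_f"}),
                on=key,
                how="inner",
            )
        )
        with np.errstate(divide="ignore"):
            s_db = 10.0 * np.log10(m["_s"].to_numpy())
        f = m["_f"].to_numpy(dtype=float)
        if fcol == density_col:  # functional given as raw density, not dB
            with np.errstate(divide="ignore"):
                f = 10.0 * np.log10(f)
        d = s_db - f
        d = d[np.isfinite(d)]
        out["rmse_density_db"] = float(np.sqrt(np.mean(d**2)))
    return out


# ---------------------------------------------------------------------------
# Test-retest noise and error stratification
# ---------------------------------------------------------------------------

def test_retest_noise(observations: pd.DataFrame) -> float:
    """Pooled test-retest SD (dB) from repeated tests of the same stimulus.

    The natural lower bound for model fitting error: for each
    eye/location/stimulus with >= 2 repeats, the between-repeat variance is
    pooled and its square root returned.
    """
    g = observations.groupby(["eye_id", "x_deg", "y_deg", "stimulus"])[
        "sensitivity_db"
    ]
    var = g.var(ddof=1)
    counts = g.count()
    var = var[counts >= 2]
    if var.empty:
        raise ValueError("no repeated tests found")
    return float(np.sqrt(var.mean()))


def error_by_sensitivity_bin(
    observed,
    predicted,
    bin_width_db: float = 4.0,
    max_db: float = 40.0,
) -> pd.DataFrame:
    """RMSE of predictions stratified by observed-sensitivity bins."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    edges = np.arange(0.0, max_db + bin_width_db, bin_width_db)
    idx = np.clip(np.digitize(obs, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        m = idx == b
        if not m.any():
            continue
        rows.append(
            {
                "bin_lo_db": edges[b],
                "bin_hi_db": edges[b + 1],
                "n": int(m.sum()),
                "rmse": float(np.sqrt(np.mean((obs[m] - pred[m]) ** 2))),
            }
        )
    return pd.DataFrame(rows)
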