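"""Survival validation of the methylation score.

Kaplan–Meier curves, log-rank and Gehan–Breslow–Wilcoxon tests, Cox
proportional-hazards fits (Efron tie handling) with Harrell concordance,
the Breslow-depth dichotomy (T1/T2 vs T3/T4, 2 mm cut) and the
score x Breslow interaction model.  Estimation is delegated to lifelines;
this module fixes the conventions (groupings, tie handling, reporting) the
pipeline relies on.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test

from .data_io import PatientRecord
from .signature import SignatureResult


@dataclasses.dataclass
class SurvivalFit:
    """Kaplan–Meier curves per group with medians and two rank tests."""

    group_labels: tuple[str, ...]
    km_curves: dict[str, pd.DataFrame]  # columns: time, survival, at_risk
    median_os: dict[str, Optional[float]]
    logrank_stat: Optional[float] = None
    logrank_p: Optional[float] = None
    gbw_stat: Optional[float] = None
    gbw_p: Optional[float] = None


@dataclasses.dataclass
class CoxFit:
    covariates: tuple[str, ...]
    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    ci95: dict[str, tuple[float, float]]  # on the hazard-ratio scale
    p_values: dict[str, float]
    concordance: float
    separation_warning: bool = False


def km_estimate(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
) -> SurvivalFit:
    """Product-limit estimate per group; median = first time S(t) <= 0.5."""
    df = pd.DataFrame({"time": times, "event": events, "group": groups})
    if df.empty:
        raise ValueError("no observations")
    if (df["time"] < 0).any():
        raise ValueError("negative survival times")
    labels = tuple(sorted(df["group"].unique()))
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, Optional[float]] = {}
    for g in labels:
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        ev = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        curves[g] = pd.DataFrame(
            {
                "time": ev.index.to_numpy(dtype=float),
                "survival": surv.reindex(ev.index).to_numpy(dtype=float),
                "at_risk": ev["at_risk"].to_numpy(dtype=int),
            }
        )
        med = kmf.median_survival_time_
        medians[g] = None if np.isinf(med) else float(med)
    return SurvivalFit(group_labels=labels, km_curves=curves, median_os=medians)


def logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence[str],
    weighting: str = "logrank",
) -> tuple[float, float]:
    """Log-rank (or Gehan–Breslow–Wilcoxon) comparison of survival curves.

    ``weighting='gehan'`` weights each event time by the number at risk.
    Returns (statistic, p); (nan, nan) when there are no events.
    """
    if weighting not in ("logrank", "gehan"):
        raise ValueError(f"unknown weighting {weighting!r}")
    df = pd.DataFrame({"time": times, "event": events, "group": groups})
    if int(df["event"].sum()) == 0:
        return float("nan"), float("nan")
    w = None if weighting == "logrank" else "wilcoxon"
    labels = sorted(df["group"].unique())
    if len(labels) == 2:
        a = df[df["group"] == labels[0]]
        b = df[df["group"] == labels[1]]
        res = _ll_logrank(
            a["time"], b["time"],
            event_observed_A=a["event"], event_observed_B=b["event"],
            weightings=w,
        )
    else:
        res = multivariate_logrank_test(
            df["time"], df["group"], df["event"], weightings=w
        )
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    times: Sequence[float],
    events: Sequence[int],
    covariates: pd.DataFrame,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) with Harrell concordance.

    Monotone likelihood (perfect separation) is flagged, not raised; the
    reported coefficient is then the point where the optimizer stopped.
    """
    covariates = covariates.reset_index(drop=True)
    const = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=int)
    cph = CoxPHFitter()
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="_time", event_col="_event")
        for wmsg in caught:
            if "convergence" in str(wmsg.message).lower() or "monotone" in str(
                wmsg.message
            ).lower():
                separation = True
    summ = cph.summary
    return CoxFit(
        covariates=tuple(covariates.columns),
        coefficients={c: float(summ.loc[c, "coef"]) for c in covariates.columns},
        hazard_ratios={c: float(np.exp(summ.loc[c, "coef"])) for c in covariates.columns},
        ci95={
            c: (
                float(np.exp(summ.loc[c, "coef lower 95%"])),
                float(np.exp(summ.loc[c, "coef upper 95%"])),
            )
            for c in covariates.columns
        },
        p_values={c: float(summ.loc[c, "p"]) for c in covariates.columns},
        concordance=float(cph.concordance_index_),
        separation_warning=separation,
    )


def breslow_groups(
    patients: Sequence[PatientRecord],
) -> tuple[dict[str, str], list[str]]:
    """Dichotomise by tumour depth: LOW = T1/T2 (or < 2 mm), HIGH = T3/T4
    (or >= 2 mm); patients with neither stage nor depth are excluded."""
    groups: dict[str, str] = {}
    excluded: list[str] = []
    for p in patients:
        if p.t_stage in ("T1", "T2"):
            groups[p.patient_id] = "LOW"
        elif p.t_stage in ("T3", "T4"):
            groups[p.patient_id] = "HIGH"
        elif p.breslow_mm is not None:
            groups[p.patient_id] = "LOW" if p.breslow_mm < 2.0 else "HIGH"
        else:
            excluded.append(p.patient_id)
    return groups, excluded


def validate_signature(
    patients: Sequence[PatientRecord],
    results: Sequence[SignatureResult],
    max_missing_genes: int = 1,
) -> dict:
    """Full survival validation of the score on the primary cohort.

    KM + log-rank + Gehan–Breslow–Wilcoxon for high-risk vs low-risk, Cox
    hazard ratios for the score, the Breslow group, and their interaction,
    each with Harrell concordance.  Patients missing more than
    ``max_missing_genes`` signature genes are excluded.
    """
    by_id = {r.patient_id: r for r in results}
    rows = []
    for p in patients:
        r = by_id.get(p.patient_id)
        if r is None or p.sample_type != "primary":
            continue
        if r.n_missing_genes > max_missing_genes:
            continue
        rows.append(
            {
                "patient_id": p.patient_id,
                "time": p.os_months,
                "event": p.event,
                "high_risk": int(r.high_risk),
                "patient": p,
            }
        )
    if not rows:
        raise ValueError("no scorable primary patients")
    df = pd.DataFrame(rows)
    bres, excluded = breslow_groups([row["patient"] for row in rows])
    df["breslow_high"] = df["patient_id"].map(
        lambda pid: {"LOW": 0, "HIGH": 1}.get(bres.get(pid))
    )

    report: dict = {"n_patients": len(df), "breslow_excluded": excluded}
    groups = np.where(df["high_risk"] == 1, "score>=2", "score<2")
    report["group_sizes"] = pd.Series(groups).value_counts().to_dict()
    if df["high_risk"].nunique() < 2:
        report["skipped"] = "one risk group is empty; group comparison skipped"
        return report

    fit = km_estimate(df["time"], df["event"], groups)
    fit.logrank_stat, fit.logrank_p = logrank(df["time"], df["event"], groups, "logrank")
    fit.gbw_stat, fit.gbw_p = logrank(df["time"], df["event"], groups, "gehan")
    report["km"] = fit
    report["median_os"] = fit.median_os
    report["logrank_p"] = fit.logrank_p
    report["gbw_p"] = fit.gbw_p

    report["cox_score"] = cox_fit(df["time"], df["event"], df[["high_risk"]])

    sub = df.dropna(subset=["breslow_high"]).copy()
    if sub["breslow_high"].nunique() == 2:
        sub["breslow_high"] = sub["breslow_high"].astype(int)
        report["cox_breslow"] = cox_fit(sub["time"], sub["event"], sub[["breslow_high"]])
        inter = sub[["high_risk", "breslow_high"]].copy()
        inter["score_x_breslow"] = inter["high_risk"] * inter["breslow_high"]
        if inter["score_x_breslow"].nunique() == 2:
            report["cox_interaction"] = cox_fit(sub["time"], sub["event"], inter)
        else:
            report["cox_interaction"] = None
    else:
        report["cox_breslow"] = None
        report["cox_interaction"] = None
    return report
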