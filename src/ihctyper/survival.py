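"""Survival stratification: Kaplan-Meier, log-rank, and Cox models.

Overall survival of resected patients is analyzed by immunohistochemical
tumor type and by anatomy-based diagnosis: Kaplan-Meier curves with median
OS (or the restricted mean when the median is not reached), log-rank tests,
and Cox proportional-hazards models giving crude hazard ratios and ratios
adjusted for pathological tumor stage (pT) and lymph node status (pN).
The proportional-hazards assumption is checked with the scaled
Schoenfeld-residual correlation test.

Conventions: one record per patient (a resection specimen's type label
wins over biopsies); pTis and pNX records are excluded from model fits;
pN1 and pN2 are merged; age is dichotomized at the cohort median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats

__all__ = [
    "CoxFit",
    "KmEstimate",
    "attach_types",
    "km_estimate",
    "logrank_test",
    "cox_model",
    "ph_assumption",
    "survival_report",
    "DEFAULT_BASELINES",
]

REQUIRED_COLUMNS = ("patient_id", "os_months", "event")

DEFAULT_BASELINES = {
    "ihc_type": "EPB",
    "diagnosis": "pancreatic_ductal",
    "pT": "T3",
    "pN": "N1_2",
    "sex": "F",
}

#: Levels never entered into model fits (no hazard ratio is estimable /
#: reported for them).
EXCLUDED_LEVELS = {"pT": ("Tis",), "pN": ("NX",)}


def _validate_records(records: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"clinical records lack required column {col!r}")
    if (records["os_months"] <= 0).any():
        raise ValueError("os_months must be > 0")
    if records["patient_id"].duplicated().any():
        raise ValueError("one record per patient required")


@dataclass
class KmEstimate:
    groups: pd.DataFrame  # per group: n, events, median_os, median_reached, restricted_mean
    curves: dict = field(default_factory=dict)  # group -> survival function DataFrame


@dataclass
class CoxFit:
    summary: pd.DataFrame  # per non-baseline level: hr, ci_lower, ci_upper, p
    global_p: float  # likelihood-ratio test
    baselines: dict
    covariates: list
    n: int
    n_events: int
    fitter: CoxPHFitter = None
    design: pd.DataFrame = None


def attach_types(
    clinical: pd.DataFrame,
    assignment: pd.Series,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Attach one tumor-type label per patient.

    ``assignment`` is per sample; patients with several samples get their
    resection specimen's label, or failing that the first biopsy's.
    """
    per_sample = pd.DataFrame(
        {
            "patient_id": meta["patient_id"],
            "probe_type": meta["probe_type"],
            "label": assignment.reindex(meta.index),
        }
    )
    per_sample["is_resection"] = (per_sample["probe_type"] == "resection").astype(int)
    per_sample = per_sample.sort_values(["patient_id", "is_resection"], kind="stable")
    chosen = per_sample.groupby("patient_id").last()["label"]
    out = clinical.copy()
    out["ihc_type"] = out["patient_id"].map(chosen)
    return out


def km_estimate(records: pd.DataFrame, grouping: str) -> KmEstimate:
    """Product-limit survival per group with median OS.

    The median is the first time at which S(t) <= 0.5; when it is never
    reached within follow-up the restricted mean survival time over the
    observed follow-up window is reported instead, flagged by
    ``median_reached = False``.
    """
    _validate_records(records)
    if records["event"].sum() < 1:
        raise ValueError("no events in records")
    horizon = float(records["os_months"].max())
    rows, curves = [], {}
    for name, sub in records.groupby(grouping):
        if sub.empty:
            raise ValueError(f"empty group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_months"], sub["event"], label=str(name))
        median = kmf.median_survival_time_
        reached = np.isfinite(median)
        rmean = float(restricted_mean_survival_time(kmf, t=horizon))
        rows.append(
            {
                "group": name,
                "n": len(sub),
                "events": int(sub["event"].sum()),
                "median_os": float(median) if reached else np.nan,
                "median_reached": bool(reached),
                "restricted_mean": rmean,
            }
        )
        curves[name] = kmf.survival_function_
    return KmEstimate(groups=pd.DataFrame(rows).set_index("group"), curves=curves)


def logrank_test(records: pd.DataFrame, grouping: str) -> tuple[float, float]:
    """Log-rank chi-square test across the groups of ``grouping``."""
    _validate_records(records)
    groups = records[grouping]
    if groups.nunique() < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(records["os_months"], groups, records["event"])
    return float(res.test_statistic), float(res.p_value)


def _build_design(
    records: pd.DataFrame, covariates: list[str], baselines: dict
) -> pd.DataFrame:
    df = records.copy()
    for cov in covariates:
        for level in EXCLUDED_LEVELS.get(cov, ()):
            df = df[df[cov] != level]
    cols = {}
    for cov in covariates:
        series = df[cov]
        if pd.api.types.is_numeric_dtype(series) and series.nunique() > 5:
            cols[cov] = series.astype(float)
            continue
        base = baselines.get(cov)
        levels = [l for l in pd.unique(series) if l != base]
        if base is not None and base not in set(series):
            raise ValueError(f"baseline {base!r} absent from covariate {cov!r}")
        if base is None:
            base = sorted(pd.unique(series))[0]
            levels = [l for l in pd.unique(series) if l != base]
        for level in sorted(map(str, levels)):
            cols[f"{cov}::{level}"] = (series.astype(str) == level).astype(float)
    design = pd.DataFrame(cols, index=df.index)
    design["os_months"] = df["os_months"].astype(float)
    design["event"] = df["event"].astype(int)
    return design


def cox_model(
    records: pd.DataFrame,
    covariates: list[str],
    baselines: dict | None = None,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron tie handling, Wald CIs).

    Categorical covariates are dummy-coded against the stated baselines
    (type: EPB, anatomy: ductal pancreatic, pT: T3, pN: N1/2); pTis and
    pNX records are dropped before fitting.  Returns hazard ratios with
    95% Wald confidence intervals and per-level Wald p-values, plus the
    likelihood-ratio global p.  Non-convergence raises rather than being
    silently clipped.
    """
    _validate_records(records)
    baselines = {**DEFAULT_BASELINES, **(baselines or {})}
    design = _build_design(records, covariates, baselines)
    n_params = design.shape[1] - 2
    n_events = int(design["event"].sum())
    if n_events < n_params:
        raise ValueError(
            f"too few events ({n_events}) for {n_params} parameters"
        )
    cph = CoxPHFitter()
    cph.fit(design, duration_col="os_months", event_col="event")
    summ = cph.summary
    out = pd.DataFrame(
        {
            "hr": np.exp(summ["coef"]),
            "ci_lower": np.exp(summ["coef lower 95%"]),
            "ci_upper": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    )
    global_p = float(cph.log_likelihood_ratio_test().p_value)
    return CoxFit(
        summary=out,
        global_p=global_p,
        baselines=baselines,
        covariates=list(covariates),
        n=design.shape[0],
        n_events=n_events,
        fitter=cph,
        design=design,
    )


def ph_assumption(fit: CoxFit, time_transform: str = "rank") -> pd.DataFrame:
    """Scaled Schoenfeld-residual test of proportional hazards.

    For transform g(t) of the event times (default: ranks), the test
    correlates g with the scaled Schoenfeld residuals; returns one chi-
    square and p per covariate column plus a joint ``GLOBAL`` row.  A
    global p above 0.05 indicates no evidence against proportionality.
    """
    cph, design = fit.fitter, fit.design
    resid = cph.compute_residuals(design, kind="schoenfeld")
    times = design.loc[resid.index, "os_months"].to_numpy(dtype=float)
    order = np.argsort(times, kind="stable")
    S = resid.to_numpy(dtype=float)[order]
    times = times[order]
    d = S.shape[0]
    if time_transform == "rank":
        # rank of each event among the ordered event times (mid-ranks for
        # tied death times)
        g = stats.rankdata(times)
    elif time_transform == "identity":
        g = times.copy()
    elif time_transform == "log":
        g = np.log(times)
    else:
        raise ValueError(f"unknown time transform {time_transform!r}")
    z = g - g.mean()
    V = cph.variance_matrix_.to_numpy(dtype=float)
    scaled = d * (S @ V)  # scaled Schoenfeld residuals (minus beta-hat)
    u = z @ scaled  # per-covariate correlation sums
    denom = d * np.sum(z**2)
    rows = {}
    for j, name in enumerate(resid.columns):
        chi2 = u[j] ** 2 / (denom * V[j, j])
        rows[name] = {"chi2": chi2, "df": 1, "p": stats.chi2.sf(chi2, 1)}
    chi2_global = float(u @ np.linalg.solve(V, u) / denom)
    p_global = stats.chi2.sf(chi2_global, S.shape[1])
    rows["GLOBAL"] = {"chi2": chi2_global, "df": S.shape[1], "p": p_global}
    return pd.DataFrame(rows).T


def survival_report(
    records: pd.DataFrame,
    baselines: dict | None = None,
    include_anatomy: bool = True,
) -> pd.DataFrame:
    """Clinicopathological prognostic table for resected patients.

    One block per covariate — age (dichotomized at the cohort median),
    sex, pT, pN, immunohistochemical type, and anatomical diagnosis — each
    with n, median OS, crude HR (95% CI, p) and, for the tumor-type
    blocks, HRs adjusted for pT + pN.  Requires one record per resected
    patient with an ``ihc_type`` column attached.
    """
    _validate_records(records)
    if "resected" in records.columns:
        df = records[records["resected"].astype(bool)].copy()
    else:
        df = records.copy()
    if df.empty:
        raise ValueError("no resected patients")
    baselines = {**DEFAULT_BASELINES, **(baselines or {})}
    age_median = float(df["age"].median())
    df["age_group"] = np.where(df["age"] > age_median, f">{age_median:g}", f"<={age_median:g}")
    baselines = {**baselines, "age_group": f">{age_median:g}"}

    blocks: list[tuple[str, bool, pd.DataFrame]] = [
        ("age_group", False, df),
        ("sex", False, df),
        ("pT", False, df[~df["pT"].isin(EXCLUDED_LEVELS["pT"])]),
        ("pN", False, df[~df["pN"].isin(EXCLUDED_LEVELS["pN"])]),
        ("ihc_type", True, df[df["ihc_type"].notna() & (df["ihc_type"] != "unclassified")]),
    ]
    if include_anatomy:
        blocks.append(("diagnosis", True, df[df["diagnosis"] != "hcc"]))

    def safe_fit(sub, covs):
        # a block with sparse cells can separate or fail to converge; the
        # report then carries NaN ratios for that block instead of aborting
        try:
            return cox_model(sub, covs, baselines)
        except Exception as exc:  # ConvergenceError, LinAlgError, ValueError
            import warnings

            warnings.warn(f"Cox fit failed for block {covs}: {exc}")
            return None

    rows = []
    for col, adjusted, sub in blocks:
        if sub[col].nunique() < 2:
            continue
        km = km_estimate(sub, col)
        crude = safe_fit(sub, [col])
        adj = safe_fit(sub, [col, "pT", "pN"]) if adjusted else None
        for level in km.groups.index:
            key = f"{col}::{level}"
            row = {
                "block": col,
                "level": level,
                "n": int(km.groups.loc[level, "n"]),
                "median_os": km.groups.loc[level, "median_os"],
                "median_reached": km.groups.loc[level, "median_reached"],
                "restricted_mean": km.groups.loc[level, "restricted_mean"],
                "crude_hr": np.nan,
                "crude_ci_lower": np.nan,
                "crude_ci_upper": np.nan,
                "crude_p": np.nan,
                "adj_hr": np.nan,
                "adj_ci_lower": np.nan,
                "adj_ci_upper": np.nan,
                "adj_p": np.nan,
                "is_baseline": level == baselines.get(col),
            }
            if crude is not None and key in crude.summary.index:
                c = crude.summary.loc[key]
                row.update(
                    crude_hr=c["hr"],
                    crude_ci_lower=c["ci_lower"],
                    crude_ci_upper=c["ci_upper"],
                    crude_p=c["p"],
                )
            elif crude is not None and row["is_baseline"]:
                row["crude_hr"] = 1.0
            if adj is not None and key in adj.summary.index:
                a = adj.summary.loc[key]
                row.update(
                    adj_hr=a["hr"],
                    adj_ci_lower=a["ci_lower"],
                    adj_ci_upper=a["ci_upper"],
                    adj_p=a["p"],
                )
            elif adj is not None and row["is_baseline"]:
                row["adj_hr"] = 1.0
            rows.append(row)
    return pd.DataFrame(rows)
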