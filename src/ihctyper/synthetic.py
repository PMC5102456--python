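"""Synthetic cohorts with the statistical structure of pancreatobiliary IHC data.

The generator emulates four marker-profile archetypes — extrahepatic
pancreatobiliary (EPB), intestinal (INT), intrahepatic cholangiocarcinoma
(ICC), and hepatocellular carcinoma (HCC, the control group) — with discrete
0-100 staining scores, panel-driven block missingness (a retrospective
diagnostic series never stains every sample with every antibody), and
type-dependent overall survival under a proportional-hazards model.

Positivity probabilities for the eight diagnostic-panel markers are derived
from the panel categories via a fixed category->probability map
(``+`` 0.90, ``+/-`` 0.60, ``-/+`` 0.30, ``-`` 0.05), so that archetypes are
separable yet overlapping, as real tumor types are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .core_data import ScoreMatrix
from .panel import TYPES, PANEL_MARKERS, default_panel

__all__ = [
    "CATEGORY_PROBABILITY",
    "TypeProfile",
    "CohortSpec",
    "default_profiles",
    "generate_scores",
    "inject_missingness",
    "generate_clinical",
    "generate_cohort",
]

#: Expectation category -> positivity probability.
CATEGORY_PROBABILITY = {"+": 0.90, "+/-": 0.60, "-/+": 0.30, "-": 0.05}

#: Extra discriminant markers beyond the 8-marker diagnostic panel, with
#: per-type positivity probabilities (EPB, INT, ICC, HCC).  These encode the
#: qualitative immunoprofiles of the archetypes: cytokeratins/mucins high in
#: EPB, CK7 in ~70% and CK17 in ~25% of intestinal tumors, generic
#: adenocarcinoma markers plus vimentin/WT1 in ICC, and a near-null
#: epithelial-adenocarcinoma profile in HCC.
EXTENDED_MARKERS = {
    "CK7":      (0.95, 0.70, 0.90, 0.05),
    "CK17":     (0.90, 0.25, 0.30, 0.05),
    "MUC1":     (0.90, 0.50, 0.60, 0.05),
    "MUC6":     (0.50, 0.20, 0.10, 0.02),
    "CDX2":     (0.30, 0.90, 0.05, 0.02),
    "vimentin": (0.05, 0.05, 0.60, 0.20),
    "WT1":      (0.05, 0.05, 0.60, 0.10),
    "maspin":   (0.90, 0.60, 0.30, 0.05),
    "BerEP4":   (0.90, 0.90, 0.90, 0.05),
    "EMA":      (0.90, 0.85, 0.85, 0.10),
    "pCEA":     (0.70, 0.80, 0.90, 0.60),
    "CK18":     (0.95, 0.95, 0.95, 0.90),
    "CK5":      (0.15, 0.05, 0.10, 0.02),
    "p63":      (0.10, 0.05, 0.05, 0.02),
    "p53":      (0.60, 0.50, 0.30, 0.20),
    "Ki67":     (0.90, 0.90, 0.80, 0.60),
    "chromograninA": (0.10, 0.10, 0.05, 0.02),
    "CD10":     (0.10, 0.30, 0.10, 0.50),
    "CD56":     (0.05, 0.05, 0.30, 0.10),
}

#: Exclusion work-up antibodies: ordered only for selected differential
#: diagnoses (ruling out lung, breast, gynecologic, melanocytic or
#: neuroendocrine primaries), hence analyzed on few samples and mostly
#: negative in pancreatobiliary disease.  They emulate the raw-dataset
#: markers that fall to the missingness pruning step.
WORKUP_MARKERS = {
    "TTF1":          (0.02, 0.02, 0.02, 0.02),
    "napsinA":       (0.02, 0.02, 0.02, 0.02),
    "GATA3":         (0.05, 0.05, 0.05, 0.02),
    "PAX8":          (0.02, 0.02, 0.05, 0.02),
    "ER":            (0.02, 0.05, 0.02, 0.02),
    "PR":            (0.02, 0.02, 0.02, 0.02),
    "S100":          (0.05, 0.02, 0.05, 0.05),
    "synaptophysin": (0.08, 0.08, 0.05, 0.05),
    "CK14":          (0.10, 0.05, 0.05, 0.02),
    "CK903":         (0.15, 0.10, 0.10, 0.05),
    "HepPar1":       (0.05, 0.05, 0.10, 0.90),
}

#: Anatomical-diagnosis mixture per archetype (EPB spans the extrahepatic
#: pancreatobiliary sites; INT is an admixture of pancreas/ampulla/gallbladder;
#: ICC and HCC map one-to-one to their liver diagnoses).
DIAGNOSIS_MIX = {
    "EPB": {
        "pancreatic_ductal": 0.55,
        "gallbladder": 0.15,
        "ampullary": 0.10,
        "perihilar_cc": 0.12,
        "distal_bile_duct": 0.08,
    },
    "INT": {"ampullary": 0.40, "pancreatic_ductal": 0.35, "gallbladder": 0.25},
    "ICC": {"intrahepatic_cc": 1.0},
    "HCC": {"hcc": 1.0},
}


@dataclass
class TypeProfile:
    """Score-generating archetype for one tumor type.

    Each marker has a positivity probability; positive scores are drawn from
    a truncated normal above the positivity threshold, negative scores from
    a truncated normal near zero, both rounded to integer percentages.
    """

    type_label: str
    positivity: dict[str, float]
    positive_dist: tuple[float, float] = (70.0, 20.0)  # mean, sd on (thr, 100]
    negative_dist: tuple[float, float] = (2.0, 3.0)    # mean, sd on [0, thr]

    def __post_init__(self) -> None:
        for g, p in self.positivity.items():
            if not (0 <= p <= 1):
                raise ValueError(f"positivity probability for {g} outside [0,1]: {p}")


@dataclass
class CohortSpec:
    """Study-shaped defaults for the synthetic cohort.

    Cohort sizes mirror the study series (a large extrahepatic
    pancreatobiliary majority, a small intestinal group, 97 ICC, 78 HCC);
    the default missingness rate of 0.36 with the ``marker_block`` mechanism
    emulates the raw dataset before pruning.  Survival defaults place the
    EPB median near 24 months with hazard ratios 0.19 (INT) and 0.61 (ICC)
    against it, and pT/pN effects matching the reported crude estimates.
    """

    n_per_type: dict[str, int] = field(
        default_factory=lambda: {"EPB": 240, "INT": 24, "ICC": 97, "HCC": 78}
    )
    missing_rate: float = 0.36
    missing_mechanism: str = "marker_block"  # or "cell_mcar"
    block_size: int | None = None
    #: per-sample missing rates drawn Beta(mean=missing_rate, this
    #: concentration) instead of being constant — biopsies with scant
    #: tissue lose most of their panel; None = homogeneous rates
    sample_rate_concentration: float | None = None
    extended_markers: bool = True
    #: add the 11 exclusion work-up antibodies, each analyzed on only
    #: ``workup_analyzed_fraction`` of samples (raw-dataset emulation)
    workup_markers: bool = False
    workup_analyzed_fraction: float = 0.18
    positivity_threshold: float = 10.0
    probe_resection_prob: float = 0.35
    two_sample_fraction: float = 0.0  # fraction of patients with biopsy + resection

    # survival model: baseline is the hazard of an EPB patient at the
    # reference stage (pT3, pN1/2); calibrated so that after mixing over
    # the pT/pN distribution the marginal EPB median OS is ~24 months
    baseline_hazard: float = log(2) / 15.7  # per month
    type_log_hr: dict[str, float] = field(
        default_factory=lambda: {
            "EPB": 0.0,
            "INT": log(0.19),
            "ICC": log(0.61),
            "HCC": log(0.50),
        }
    )
    censoring_rate: float = 0.30
    pt_probs: dict[str, float] = field(
        default_factory=lambda: {"T1": 0.12, "T2": 0.31, "T3": 0.46, "T4": 0.11}
    )
    pt_log_hr: dict[str, float] = field(
        default_factory=lambda: {
            "T1": log(0.46),
            "T2": log(0.75),
            "T3": 0.0,
            "T4": log(3.37),
        }
    )
    pn_probs: dict[str, float] = field(default_factory=lambda: {"N0": 0.37, "N1_2": 0.63})
    pn_log_hr: dict[str, float] = field(default_factory=lambda: {"N0": log(0.36), "N1_2": 0.0})
    age_mean: float = 66.0
    age_sd: float = 10.0
    female_prob: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if all(n == 0 for n in self.n_per_type.values()):
            raise ValueError("empty cohort spec: all n_per_type are zero")
        if any(n < 0 for n in self.n_per_type.values()):
            raise ValueError("n_per_type must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0,1)")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0,1)")
        if self.missing_mechanism not in {"cell_mcar", "marker_block"}:
            raise ValueError(f"unknown missing_mechanism {self.missing_mechanism!r}")


def default_profiles(extended: bool = True, workup: bool = False) -> list[TypeProfile]:
    """The four archetypes, from the diagnostic-panel grid.

    Panel categories map to positivity probabilities through
    :data:`CATEGORY_PROBABILITY`; with ``extended=True`` the profiles also
    cover the additional discriminant markers in :data:`EXTENDED_MARKERS`
    (27 markers in total, the analyzed set), and ``workup=True`` appends
    the 11 rarely-ordered exclusion antibodies (38 markers, the raw set).
    """
    panel = default_panel()
    profiles = []
    for j, t in enumerate(TYPES):
        pos = {g: CATEGORY_PROBABILITY[panel.grid.loc[g, t]] for g in PANEL_MARKERS}
        if extended:
            pos.update({g: probs[j] for g, probs in EXTENDED_MARKERS.items()})
        if workup:
            pos.update({g: probs[j] for g, probs in WORKUP_MARKERS.items()})
        profiles.append(TypeProfile(type_label=t, positivity=pos))
    return profiles


def raw_study_spec(seed: int = 0) -> CohortSpec:
    """Cohort spec emulating the raw study dataset before pre-processing.

    439 tumor samples x 38 antibodies: the 27 analyzed markers carry
    panel-block missingness around 18% with heterogeneous per-sample rates
    (scant biopsies lose most of their panel), and the 11 exclusion
    work-up antibodies are analyzed on only a small fraction of samples —
    together yielding roughly 36% raw missingness, most of which falls to
    the >40% marker / >50% sample pruning rule.
    """
    return CohortSpec(
        seed=seed,
        missing_rate=0.18,
        sample_rate_concentration=4.0,
        workup_markers=True,
    )


def _trunc_scores(rng, lo, hi, mean, sd, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_scores(
    profiles: list[TypeProfile],
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> tuple[ScoreMatrix, pd.Series]:
    """Draw a complete score matrix plus true type labels.

    Per sample and marker a Bernoulli draw at the profile's positivity
    probability chooses the positive or negative score component; scores are
    truncated-normal draws rounded to integer percentages, positives
    strictly above the positivity threshold and negatives at or below it.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    by_label = {p.type_label: p for p in profiles}
    markers = list(profiles[0].positivity)
    thr = spec.positivity_threshold

    rows, labels, meta_rows, index = [], [], [], []
    counter = 0
    for t in TYPES:
        n = spec.n_per_type.get(t, 0)
        if n == 0:
            continue
        prof = by_label[t]
        diag_names = list(DIAGNOSIS_MIX[t])
        diag_p = np.array([DIAGNOSIS_MIX[t][d] for d in diag_names], dtype=float)
        diag_p /= diag_p.sum()
        p = np.array([prof.positivity[g] for g in markers])
        pos_mask = rng.random((n, len(markers))) < p
        pos_vals = np.round(
            _trunc_scores(rng, thr + 1.0, 100.0, *prof.positive_dist, size=(n, len(markers)))
        )
        neg_vals = np.round(
            _trunc_scores(rng, 0.0, thr, *prof.negative_dist, size=(n, len(markers)))
        )
        vals = np.where(pos_mask, pos_vals, neg_vals)
        diags = rng.choice(diag_names, size=n, p=diag_p)
        probes = np.where(
            rng.random(n) < spec.probe_resection_prob, "resection", "biopsy"
        )
        for i in range(n):
            counter += 1
            sid = f"S{counter:04d}"
            index.append(sid)
            rows.append(vals[i])
            labels.append(t)
            meta_rows.append((f"P{counter:04d}", diags[i], probes[i]))

    idx = pd.Index(index, name="sample_id")
    scores = pd.DataFrame(np.asarray(rows, dtype=float), index=idx, columns=markers)
    meta = pd.DataFrame(meta_rows, index=idx, columns=["patient_id", "diagnosis", "probe_type"])
    m = ScoreMatrix(scores, meta)

    if spec.two_sample_fraction > 0:
        m = _add_duplicate_samples(m, labels, spec, rng)
        labels = list(m.meta["true_type"]) if "true_type" in m.meta else labels
    truth = pd.Series(labels, index=m.scores.index, name="true_type")
    return m, truth


def _add_duplicate_samples(m, labels, spec, rng):
    # a fraction of biopsy patients gain a second (resection) sample with the
    # same metadata; scores are copied with small re-scoring noise
    scores, meta = m.scores.copy(), m.meta.copy()
    meta["true_type"] = labels
    biopsy_ids = [s for s in m.sample_ids if m.meta.loc[s, "probe_type"] == "biopsy"]
    n_dup = int(round(spec.two_sample_fraction * len(biopsy_ids)))
    chosen = rng.choice(biopsy_ids, size=n_dup, replace=False) if n_dup else []
    for sid in chosen:
        new_id = f"{sid}R"
        noise = rng.normal(0, 5, size=m.n_markers)
        scores.loc[new_id] = np.clip(np.round(scores.loc[sid].to_numpy() + noise), 0, 100)
        meta.loc[new_id] = meta.loc[sid]
        meta.loc[new_id, "probe_type"] = "resection"
    return ScoreMatrix(scores, meta)


def inject_missingness(
    m: ScoreMatrix,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> ScoreMatrix:
    """Mask cells according to the spec's missingness mechanism.

    ``cell_mcar`` masks each cell independently at ``missing_rate``.
    ``marker_block`` emulates panel-driven missingness in a retrospective
    diagnostic series: each sample loses a whole block of markers (the
    antibodies that were never ordered for it).  With ``block_size`` unset
    the per-sample block size is randomized around ``missing_rate x
    n_markers`` so the realized overall missingness matches the rate.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    rate = spec.missing_rate
    scores = m.scores.copy()
    n = scores.shape[0]

    # work-up antibodies: each analyzed on only a fraction of samples,
    # independent of the core panel's missingness rate
    workup_cols = (
        [g for g in scores.columns if g in WORKUP_MARKERS]
        if spec.workup_markers
        else []
    )
    for gname in workup_cols:
        analyzed = rng.random(n) < spec.workup_analyzed_fraction
        scores.loc[~analyzed, gname] = np.nan

    core = [g for g in scores.columns if g not in set(workup_cols)]
    g = len(core)
    if rate == 0 or g == 0:
        return ScoreMatrix(scores, m.meta.copy())
    core_idx = [scores.columns.get_loc(c) for c in core]

    if spec.missing_mechanism == "cell_mcar":
        mask = rng.random((n, g)) < rate
        sub = scores.iloc[:, core_idx].to_numpy()
        sub[mask] = np.nan
        scores.iloc[:, core_idx] = sub
    elif spec.block_size is not None:
        b = int(spec.block_size)
        p_affect = min(1.0, rate * g / b)
        for i in range(n):
            if rng.random() < p_affect:
                cols = rng.choice(core_idx, size=b, replace=False)
                scores.iloc[i, cols] = np.nan
    else:
        if spec.sample_rate_concentration is not None:
            kappa = spec.sample_rate_concentration
            rates = rng.beta(rate * kappa, (1 - rate) * kappa, size=n)
        else:
            rates = np.full(n, rate)
        for i in range(n):
            target = rates[i] * g
            b = int(np.floor(target)) + (1 if rng.random() < target % 1 else 0)
            if b > 0:
                cols = rng.choice(core_idx, size=min(b, g), replace=False)
                scores.iloc[i, cols] = np.nan
    return ScoreMatrix(scores, m.meta.copy())


def _draw_categories(rng, probs: Mapping[str, float], size: int) -> np.ndarray:
    names = list(probs)
    p = np.array([probs[k] for k in names], dtype=float)
    p /= p.sum()
    return rng.choice(names, size=size, p=p)


def generate_clinical(
    labels: pd.Series,
    spec: CohortSpec,
    meta: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One clinical record per patient under a proportional-hazards model.

    The death hazard is ``baseline_hazard * exp(type effect + pT effect +
    pN effect)`` with exponential event times.  Censoring is independent
    exponential with a per-patient rate chosen so the expected censoring
    probability equals ``censoring_rate``.

    ``labels`` is indexed by sample id; ``meta`` (optional) supplies
    patient_id/diagnosis/probe_type per sample — without it each sample is
    its own patient with unknown diagnosis.
    """
    if labels.empty:
        raise ValueError("labels is empty")
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 2)

    if meta is None:
        per_patient = pd.DataFrame(
            {
                "patient_id": labels.index,
                "sample_id": labels.index,
                "true_type": labels.values,
                "diagnosis": "pancreatic_ductal",
                "resected": True,
            }
        )
    else:
        df = meta.copy()
        df["true_type"] = labels
        df["sample_id"] = df.index
        # one row per patient; a resection sample wins over biopsies
        df = df.sort_values(["patient_id", "probe_type"])  # biopsy < resection
        resected = df.groupby("patient_id")["probe_type"].apply(lambda s: (s == "resection").any())
        first = df.groupby("patient_id").last()  # resection row if present
        per_patient = pd.DataFrame(
            {
                "patient_id": first.index,
                "sample_id": first["sample_id"].values,
                "true_type": first["true_type"].values,
                "diagnosis": first["diagnosis"].values,
                "resected": resected.loc[first.index].values,
            }
        )

    n = len(per_patient)
    pt = _draw_categories(rng, spec.pt_probs, n)
    pn = _draw_categories(rng, spec.pn_probs, n)
    age = rng.normal(spec.age_mean, spec.age_sd, size=n).round(1)
    sex = np.where(rng.random(n) < spec.female_prob, "F", "M")

    log_hr = (
        np.array([spec.type_log_hr[t] for t in per_patient["true_type"]])
        + np.array([spec.pt_log_hr[c] for c in pt])
        + np.array([spec.pn_log_hr[c] for c in pn])
    )
    lam = spec.baseline_hazard * np.exp(log_hr)
    event_t = rng.exponential(1.0 / lam)
    if spec.censoring_rate > 0:
        mu = lam * spec.censoring_rate / (1 - spec.censoring_rate)
        censor_t = rng.exponential(1.0 / mu)
    else:
        censor_t = np.full(n, np.inf)
    os_months = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)

    return pd.DataFrame(
        {
            "patient_id": per_patient["patient_id"].values,
            "os_months": np.round(os_months, 2).clip(min=0.01),
            "event": event,
            "pT": pt,
            "pN": pn,
            "age": age,
            "sex": sex,
            "resected": per_patient["resected"].values,
            "sample_id": per_patient["sample_id"].values,
            "diagnosis": per_patient["diagnosis"].values,
            "true_type": per_patient["true_type"].values,
        }
    )


def generate_cohort(
    spec: CohortSpec | None = None,
    profiles: list[TypeProfile] | None = None,
) -> tuple[ScoreMatrix, pd.Series, pd.DataFrame]:
    """Full synthetic study: scores (with missingness), truth, clinical table."""
    spec = spec or CohortSpec()
    profiles = profiles or default_profiles(
        extended=spec.extended_markers, workup=spec.workup_markers
    )
    rng = np.random.default_rng(spec.seed)
    complete, truth = generate_scores(profiles, spec, rng)
    masked = inject_missingness(complete, spec, rng)
    clinical = generate_clinical(truth, spec, meta=masked.meta, rng=rng)
    return masked, truth, clinical
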