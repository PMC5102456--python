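"""Core data model for immunohistochemical (IHC) score matrices.

The central object is a :class:`ScoreMatrix`: tumor samples in rows, antibody
markers in columns, each cell either missing (the marker was not analyzed on
that sample) or a score in [0, 100] giving the percentage of stained tumor
cells.  Sample-level metadata (patient, anatomical diagnosis, probe type)
travels with the scores.

This module also owns the pre-processing conventions used throughout the
pipeline: missingness accounting, the two-step prune rule (markers with more
than 40% missing values first, then samples with more than 50% missing
values), and the positivity predicate (score strictly above 10 percent of
tumor cells).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DIAGNOSES",
    "PROBE_TYPES",
    "ScoreMatrix",
    "PipelineConfig",
    "PruneReport",
    "MissingnessSummary",
    "read_score_table",
    "write_score_table",
    "summarize_missingness",
    "prune_missing",
    "is_positive",
]

#: Anatomy-based diagnosis tokens (TNM 7th-edition primary sites plus the
#: hepatocellular-carcinoma control group).
DIAGNOSES = frozenset(
    {
        "ampullary",
        "pancreatic_ductal",
        "distal_bile_duct",
        "gallbladder",
        "perihilar_cc",
        "intrahepatic_cc",
        "hcc",
    }
)

PROBE_TYPES = frozenset({"biopsy", "resection"})

#: Reserved metadata columns in the wide table layout; everything else is a marker.
META_COLUMNS = ("sample_id", "patient_id", "diagnosis", "probe_type")


class ScoreMatrixError(ValueError):
    """Raised when a table violates the score-matrix contract."""


@dataclass
class ScoreMatrix:
    """Samples x markers IHC score matrix with sample metadata.

    Parameters
    ----------
    scores:
        DataFrame indexed by sample id, one float column per marker.
        ``NaN`` encodes "not analyzed".  Non-missing values must lie in
        [0, 100].
    meta:
        DataFrame indexed by sample id with columns ``patient_id``,
        ``diagnosis`` and ``probe_type``.
    """

    scores: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.scores.index.has_duplicates:
            dups = self.scores.index[self.scores.index.duplicated()].tolist()
            raise ScoreMatrixError(f"duplicate sample_id(s): {dups}")
        if self.scores.columns.has_duplicates:
            dups = self.scores.columns[self.scores.columns.duplicated()].tolist()
            raise ScoreMatrixError(f"duplicate marker name(s): {dups}")
        if not self.scores.index.equals(self.meta.index):
            raise ScoreMatrixError("scores and meta must share the same sample index")
        for col in ("patient_id", "diagnosis", "probe_type"):
            if col not in self.meta.columns:
                raise ScoreMatrixError(f"metadata column {col!r} missing")
        bad_diag = set(self.meta["diagnosis"]) - DIAGNOSES
        if bad_diag:
            raise ScoreMatrixError(f"unknown diagnosis token(s): {sorted(bad_diag)}")
        bad_probe = set(self.meta["probe_type"]) - PROBE_TYPES
        if bad_probe:
            raise ScoreMatrixError(f"unknown probe_type token(s): {sorted(bad_probe)}")
        vals = self.scores.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out = (vals < 0) | (vals > 100)
        if np.any(out):
            r, c = np.argwhere(out)[0]
            raise ScoreMatrixError(
                f"score out of [0,100] at sample {self.scores.index[r]!r}, "
                f"marker {self.scores.columns[c]!r}: {vals[r, c]}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def marker_names(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_markers(self) -> int:
        return self.scores.shape[1]

    @property
    def observed_mask(self) -> pd.DataFrame:
        """Boolean frame: True where a score was recorded."""
        return self.scores.notna()

    @property
    def is_complete(self) -> bool:
        return bool(self.scores.notna().all().all())

    def subset(
        self,
        samples: Iterable[str] | None = None,
        markers: Iterable[str] | None = None,
    ) -> "ScoreMatrix":
        s = self.scores
        m = self.meta
        if samples is not None:
            samples = list(samples)
            s = s.loc[samples]
            m = m.loc[samples]
        if markers is not None:
            s = s.loc[:, list(markers)]
        return ScoreMatrix(s.copy(), m.copy())

    def copy(self) -> "ScoreMatrix":
        return ScoreMatrix(self.scores.copy(), self.meta.copy())

    def equals(self, other: "ScoreMatrix") -> bool:
        return (
            self.scores.equals(other.scores)
            and self.meta[list(META_COLUMNS[1:])].equals(other.meta[list(META_COLUMNS[1:])])
        )


@dataclass
class PipelineConfig:
    """Tunable constants of the typing pipeline.

    Defaults encode the published pre-processing conventions: markers with
    more than 40% missing values and samples with more than 50% missing
    values are pruned (in that order); a marker is called positive above 10
    percent stained cells; the consensus co-clustering network uses 15000
    random-imputation iterations in production.
    """

    marker_missing_threshold: float = 0.40
    sample_missing_threshold: float = 0.50
    positivity_threshold: float = 10.0
    knn_k: int = 10
    n_network_iterations: int = 15000
    n_permutations: int = 10000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.marker_missing_threshold < 1):
            raise ValueError("marker_missing_threshold must be in (0,1)")
        if not (0 < self.sample_missing_threshold < 1):
            raise ValueError("sample_missing_threshold must be in (0,1)")
        if not (0 <= self.positivity_threshold <= 100):
            raise ValueError("positivity_threshold must be in [0,100]")
        for name in ("knn_k", "n_network_iterations", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Short stable hash identifying this configuration in outputs."""
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PruneReport:
    removed_markers: list[str]
    removed_samples: list[str]
    missing_fraction_before: float
    missing_fraction_after: float


@dataclass
class MissingnessSummary:
    per_marker: pd.Series
    per_sample: pd.Series
    overall: float


# ---------------------------------------------------------------------------
# I/O


def _parse_cell(value, sample_id, marker):
    if value is None:
        return np.nan
    s = str(value).strip()
    if s == "" or s.upper() in {"NA", "NAN"}:
        return np.nan
    try:
        x = float(s)
    except ValueError:
        raise ScoreMatrixError(
            f"non-numeric score at sample {sample_id!r}, marker {marker!r}: {s!r}"
        ) from None
    if not (0 <= x <= 100):
        raise ScoreMatrixError(
            f"score out of [0,100] at sample {sample_id!r}, marker {marker!r}: {s}"
        )
    return x


def read_score_table(
    path: str | Path,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> ScoreMatrix:
    """Read a wide-format score table.

    One row per tumor sample; the reserved columns ``sample_id``,
    ``patient_id``, ``diagnosis`` and ``probe_type`` carry metadata and every
    remaining column is a marker.  Empty cells and ``NA`` encode missing.

    ``column_map`` renames input columns to the canonical schema, e.g.
    ``{"case": "sample_id"}``, to accommodate externally produced tables.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing_meta = [c for c in META_COLUMNS if c not in raw.columns]
    if missing_meta:
        raise ScoreMatrixError(f"required column(s) absent: {missing_meta}")
    markers = [c for c in raw.columns if c not in META_COLUMNS]
    if not markers:
        raise ScoreMatrixError("no marker columns found")

    sample_ids = raw["sample_id"].astype(str)
    parsed = {
        g: [
            _parse_cell(v, sid, g)
            for v, sid in zip(raw[g], sample_ids)
        ]
        for g in markers
    }
    scores = pd.DataFrame(parsed, index=pd.Index(sample_ids, name="sample_id"))
    meta = pd.DataFrame(
        {
            "patient_id": raw["patient_id"].astype(str).values,
            "diagnosis": raw["diagnosis"].astype(str).values,
            "probe_type": raw["probe_type"].astype(str).values,
        },
        index=scores.index,
    )
    return ScoreMatrix(scores, meta)


def write_score_table(m: ScoreMatrix, path: str | Path, delimiter: str | None = None) -> None:
    """Write ``m`` in the wide layout accepted by :func:`read_score_table`.

    Scores are written as shortest-repr floats and missing cells as empty
    strings, so a write/read round-trip preserves values and mask exactly.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    out = pd.concat([m.meta[list(META_COLUMNS[1:])], m.scores], axis=1)
    out.insert(0, "sample_id", m.scores.index)
    out.to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Missingness


def summarize_missingness(m: ScoreMatrix) -> MissingnessSummary:
    """Fraction of missing cells overall, per marker, and per sample."""
    if m.n_samples == 0 or m.n_markers == 0:
        raise ScoreMatrixError("empty score matrix")
    isna = m.scores.isna()
    return MissingnessSummary(
        per_marker=isna.mean(axis=0),
        per_sample=isna.mean(axis=1),
        overall=float(isna.to_numpy().mean()),
    )


def prune_missing(
    m: ScoreMatrix, cfg: PipelineConfig | None = None
) -> tuple[ScoreMatrix, PruneReport]:
    """Two-step missingness pruning.

    First markers whose missing fraction is strictly greater than
    ``marker_missing_threshold`` are dropped; then, on the reduced matrix,
    samples whose missing fraction is strictly greater than
    ``sample_missing_threshold`` are dropped.  The order matters: a sample
    may be rescued by the removal of its unanalyzed markers.
    """
    cfg = cfg or PipelineConfig()
    before = summarize_missingness(m).overall

    marker_frac = m.scores.isna().mean(axis=0)
    removed_markers = list(marker_frac.index[marker_frac > cfg.marker_missing_threshold])
    kept_markers = [g for g in m.marker_names if g not in set(removed_markers)]
    if not kept_markers:
        raise ScoreMatrixError("empty after pruning: all markers removed")

    reduced = m.scores[kept_markers]
    sample_frac = reduced.isna().mean(axis=1)
    removed_samples = list(sample_frac.index[sample_frac > cfg.sample_missing_threshold])
    kept_samples = [s for s in m.sample_ids if s not in set(removed_samples)]
    if not kept_samples:
        raise ScoreMatrixError("empty after pruning: all samples removed")

    pruned = m.subset(samples=kept_samples, markers=kept_markers)
    report = PruneReport(
        removed_markers=removed_markers,
        removed_samples=removed_samples,
        missing_fraction_before=before,
        missing_fraction_after=summarize_missingness(pruned).overall,
    )
    return pruned, report


# ---------------------------------------------------------------------------
# Positivity


def is_positive(score: float | None, threshold: float = 10.0) -> str:
    """Positivity call for one score.

    A sample is *positive* for a marker when immunoreactivity is seen in
    strictly more than ``threshold`` percent of tumor cells; a missing score
    yields ``"unknown"``.
    """
    if not (0 <= threshold <= 100):
        raise ValueError("threshold must be in [0,100]")
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return "unknown"
    return "positive" if score > threshold else "negative"


def positivity_fractions(
    scores: pd.DataFrame, threshold: float = 10.0
) -> tuple[pd.Series, pd.Series]:
    """Per-marker positive fraction among observed cells, with counts.

    Returns ``(fraction, n_observed)``; markers with no observed score get
    ``NaN`` fraction and ``n=0``.
    """
    observed = scores.notna()
    positive = scores.gt(threshold) & observed
    n = observed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = positive.sum(axis=0) / n.replace(0, np.nan)
    return frac, n
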