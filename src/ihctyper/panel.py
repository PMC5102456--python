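"""Diagnostic immunohistochemical panel: the 8-marker x 4-type grid.

The panel summarizes the expected immunoreactivity of eight highly
discriminant markers (CK19, CK20, MUC2, MUC5AC, CA19-9, monoclonal CEA,
CA125, SMAD4) across the four immunohistochemical tumor types:

* ``EPB`` — extrahepatic pancreatobiliary
* ``INT`` — intestinal
* ``ICC`` — intrahepatic cholangiocarcinoma
* ``HCC`` — hepatocellular carcinoma (internal control group)

Categories order the expected frequency of positivity:
``"+"`` (mostly positive) > ``"+/-"`` (often positive) > ``"-/+"``
(occasionally positive) > ``"-"`` (mostly negative).  The numeric band
edges attached to the categories are a convention of this package (the
published table prints no cutoffs): ``"+"`` at positive fraction >= 0.75,
``"+/-"`` in [0.50, 0.75), ``"-/+"`` in [0.25, 0.50), ``"-"`` below 0.25.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TYPES",
    "PANEL_MARKERS",
    "CATEGORIES",
    "DEFAULT_BANDS",
    "DEFAULT_WEIGHTS",
    "DiagnosticPanel",
    "default_panel",
    "category_from_fraction",
    "derive_panel",
    "classify_sample",
]

TYPES = ("EPB", "INT", "ICC", "HCC")
PANEL_MARKERS = ("CK19", "CK20", "MUC2", "MUC5AC", "CA19-9", "mCEA", "CA125", "SMAD4")
CATEGORIES = ("+", "+/-", "-/+", "-")

# Published grid: rows are markers, columns EPB, INT, ICC, HCC.
_GRID = {
    "CK19":   ("+",   "+",   "+",   "-"),
    "CK20":   ("-/+", "+/-", "-",   "-"),
    "MUC2":   ("-",   "+/-", "-",   "-"),
    "MUC5AC": ("+/-", "-/+", "-",   "-"),
    "CA19-9": ("+",   "+",   "+/-", "-"),
    "mCEA":   ("+/-", "+",   "-",   "-"),
    "CA125":  ("+/-", "-/+", "-",   "-"),
    "SMAD4":  ("-/+", "+",   "+",   "+"),
}

#: Lower band edges on the positive fraction, by category.
DEFAULT_BANDS = {"+": 0.75, "+/-": 0.50, "-/+": 0.25, "-": 0.0}

#: Match weights used by :func:`classify_sample`: (reward if the call agrees
#: with the category's majority side, penalty otherwise).
DEFAULT_WEIGHTS = {"+": 1.0, "+/-": 0.5, "-/+": 0.5, "-": 1.0}


@dataclass
class DiagnosticPanel:
    """Marker x type grid of expectation categories with its band edges."""

    grid: pd.DataFrame  # index markers, columns types, values in CATEGORIES (or "NA")
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        bad = set(np.unique(self.grid.to_numpy())) - set(CATEGORIES) - {"NA"}
        if bad:
            raise ValueError(f"unknown panel categories: {sorted(bad)}")

    @property
    def markers(self) -> list[str]:
        return list(self.grid.index)

    @property
    def types(self) -> list[str]:
        return list(self.grid.columns)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "markers": self.markers,
            "types": self.types,
            "categories": {g: dict(self.grid.loc[g]) for g in self.markers},
            "bands": self.bands,
            "weights": self.weights,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DiagnosticPanel":
        payload = json.loads(Path(path).read_text())
        grid = pd.DataFrame(payload["categories"]).T.loc[payload["markers"], payload["types"]]
        return cls(grid, bands=payload["bands"], weights=payload["weights"])


def default_panel() -> DiagnosticPanel:
    """The published 8-marker diagnostic panel."""
    grid = pd.DataFrame.from_dict(_GRID, orient="index", columns=list(TYPES))
    return DiagnosticPanel(grid.loc[list(PANEL_MARKERS)])


def category_from_fraction(f: float, bands: dict | None = None) -> str:
    """Map a positive fraction in [0,1] to an expectation category.

    Bands are left-closed: f = 0.50 is ``"+/-"``, f = 0.75 is ``"+"``.
    """
    if not (0 <= f <= 1):
        raise ValueError(f"fraction outside [0,1]: {f}")
    bands = bands or DEFAULT_BANDS
    for cat in ("+", "+/-", "-/+"):
        if f >= bands[cat]:
            return cat
    return "-"


def derive_panel(
    profile: pd.DataFrame,
    markers: list[str] | None = None,
    bands: dict | None = None,
) -> DiagnosticPanel:
    """Build a panel from observed positivity fractions.

    ``profile`` is a marker x type DataFrame of positive fractions (as
    produced by :func:`ihctyper.diffexp.positivity_profiles`); NaN cells
    (no observed scores) become category ``"NA"`` with a warning.
    """
    import warnings

    markers = list(markers) if markers is not None else list(profile.index)
    types = [t for t in TYPES if t in profile.columns]
    grid = pd.DataFrame(index=markers, columns=types, dtype=object)
    for g in markers:
        for t in types:
            f = profile.loc[g, t]
            if pd.isna(f):
                warnings.warn(f"no observed scores for marker {g!r} in type {t}; category NA")
                grid.loc[g, t] = "NA"
            else:
                grid.loc[g, t] = category_from_fraction(float(f), bands)
    return DiagnosticPanel(grid, bands=dict(bands or DEFAULT_BANDS))


def classify_sample(
    scores: pd.Series,
    panel: DiagnosticPanel | None = None,
    positivity_threshold: float = 10.0,
    min_margin: float = 0.5,
) -> tuple[str, pd.Series, float]:
    """Assign a single sample to a tumor type by panel agreement.

    For each type, every observed panel marker contributes a match weight:
    a marker expected ``"+"`` scores +1 when the sample is positive
    (score > threshold) and -1 otherwise; ``"-"`` symmetrically; the
    intermediate categories ``"+/-"`` / ``"-/+"`` contribute +-0.5 toward
    their majority side.  Missing markers contribute 0.  The label is the
    argmax type; when the winning margin over the runner-up falls below
    ``min_margin`` the call is ``"indeterminate"``.

    Returns ``(label, per-type match scores, margin)``.
    """
    panel = panel or default_panel()
    observed = [g for g in panel.markers if g in scores.index and pd.notna(scores[g])]
    if not observed:
        raise ValueError("no observed panel markers in sample")
    totals = pd.Series(0.0, index=panel.types)
    for g in observed:
        positive = scores[g] > positivity_threshold
        for t in panel.types:
            cat = panel.grid.loc[g, t]
            if cat == "NA":
                continue
            w = panel.weights[cat]
            expects_positive = cat in ("+", "+/-")
            totals[t] += w if positive == expects_positive else -w
    ranked = totals.sort_values(ascending=False)
    margin = float(ranked.iloc[0] - ranked.iloc[1])
    top = ranked.index[0]
    label = top if margin >= min_margin else "indeterminate"
    return label, totals, margin
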