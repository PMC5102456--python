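"""Internal model validation by pairwise supervised classification.

The immunohistochemical tumor types are re-learned from the score matrix by
four classifier families — naive Bayes, L2-regularized logistic regression,
a linear max-margin classifier, and a single randomized decision tree —
under stratified k-fold cross-validation, for the three clinically relevant
pairwise tasks (EPB vs INT, EPB vs ICC, ICC vs HCC) and two feature sets
(all markers vs the consensus discriminant markers of each pair).  Stable,
high metrics across families and feature sets support the reproducibility
of the typing; the point is validation, not classifier tuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .core_data import ScoreMatrix

__all__ = ["FAMILIES", "CvMetrics", "pairwise_cv", "validation_suite"]

FAMILIES = ("naive_bayes", "logistic", "linear_margin", "random_tree")

METRICS = ("tpr", "fpr", "precision", "recall", "f", "roc_area")


def _make_classifier(family: str, seed: int):
    if family == "naive_bayes":
        return GaussianNB()
    if family == "logistic":
        return LogisticRegression(C=1.0, max_iter=2000)
    if family == "linear_margin":
        return LinearSVC(C=1.0)
    if family == "random_tree":
        return DecisionTreeClassifier(splitter="random", random_state=seed)
    raise ValueError(f"unknown classifier family {family!r}")


@dataclass
class CvMetrics:
    pair: tuple[str, str]
    family: str
    feature_set: str
    tpr: float
    fpr: float
    precision: float
    recall: float
    f: float
    roc_area: float
    n_samples: int
    n_features: int

    def as_dict(self) -> dict:
        return {
            "pair": f"{self.pair[0]}_vs_{self.pair[1]}",
            "family": self.family,
            "feature_set": self.feature_set,
            **{k: getattr(self, k) for k in METRICS},
            "n_samples": self.n_samples,
            "n_features": self.n_features,
        }


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray) -> dict:
    """Six metrics macro-averaged over the two classes."""
    out = {k: 0.0 for k in METRICS[:-1]}
    for cls in (0, 1):
        tp = np.sum((y_pred == cls) & (y_true == cls))
        fp = np.sum((y_pred == cls) & (y_true != cls))
        fn = np.sum((y_pred != cls) & (y_true == cls))
        tn = np.sum((y_pred != cls) & (y_true != cls))
        tpr = tp / (tp + fn) if tp + fn else 0.0
        fpr = fp / (fp + tn) if fp + tn else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * tpr / (prec + tpr) if prec + tpr else 0.0
        out["tpr"] += tpr / 2
        out["fpr"] += fpr / 2
        out["precision"] += prec / 2
        out["recall"] += tpr / 2
        out["f"] += f1 / 2
    out["roc_area"] = float(roc_auc_score(y_true, scores))
    return out


def pairwise_cv(
    m: ScoreMatrix,
    assignment: pd.Series,
    pair: tuple[str, str],
    family: str,
    features: list[str] | None = None,
    feature_set: str = "all",
    folds: int = 10,
    seed: int = 0,
) -> CvMetrics:
    """Stratified k-fold CV for one type pair and classifier family.

    ``features`` restricts the marker set (e.g. to a pair's consensus
    discriminant markers); every sample is tested exactly once and the
    pooled out-of-fold predictions yield the metrics.
    """
    if not m.is_complete:
        raise ValueError("score matrix must be complete (impute first)")
    assignment = assignment.reindex(m.scores.index)
    keep = assignment.isin(pair).to_numpy()
    X = m.scores.loc[keep]
    if features is not None:
        X = X[list(features)]
    y = (assignment[keep] == pair[0]).astype(int).to_numpy()
    for cls, label in ((1, pair[0]), (0, pair[1])):
        if (y == cls).sum() < folds:
            raise ValueError(f"class {label} has fewer samples than folds={folds}")

    Xv = X.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    scores = np.empty(len(y), dtype=float)
    for train, test in skf.split(Xv, y):
        clf = _make_classifier(family, seed)
        clf.fit(Xv[train], y[train])
        y_pred[test] = clf.predict(Xv[test])
        if hasattr(clf, "predict_proba"):
            scores[test] = clf.predict_proba(Xv[test])[:, 1]
        else:
            scores[test] = clf.decision_function(Xv[test])
    met = _binary_metrics(y, y_pred, scores)
    return CvMetrics(
        pair=pair,
        family=family,
        feature_set=feature_set,
        n_samples=len(y),
        n_features=X.shape[1],
        **met,
    )


def validation_suite(
    m: ScoreMatrix,
    assignment: pd.Series,
    consensus_sets: dict[tuple[str, str], list[str]] | None = None,
    pairs=(("EPB", "INT"), ("EPB", "ICC"), ("ICC", "HCC")),
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Full validation grid: pairs x families x feature sets.

    ``consensus_sets`` maps each pair to its consensus discriminant
    markers; without it only the all-marker rows are produced.  Returns one
    row per (pair, family, feature set) with the six metrics.
    """
    rows = []
    for pair in pairs:
        feature_sets = {"all": None}
        if consensus_sets is not None:
            markers = consensus_sets.get(pair, [])
            if markers:
                feature_sets["consensus"] = list(markers)
        for family in FAMILIES:
            for fs_name, feats in feature_sets.items():
                met = pairwise_cv(
                    m,
                    assignment,
                    pair,
                    family,
                    features=feats,
                    feature_set=fs_name,
                    folds=folds,
                    seed=seed,
                )
                rows.append(met.as_dict())
    return pd.DataFrame(rows)
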