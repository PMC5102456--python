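"""Hierarchical clustering of tumor samples and semi-supervised type assignment.

The analysis clusters samples with Pearson distance (1 - r between two
samples' marker-score vectors) and unweighted average linkage (UPGMA), cuts
the dendrogram into k clusters, and turns clusters into immunohistochemical
tumor-type labels with an automatable surrogate of the semi-supervised
evaluation: hepatocellular carcinoma, whose profile is well known, serves as
the internal control group — k is chosen as the smallest cut at which the
control samples concentrate in high-purity clusters — and the remaining
clusters are named from their dominant anatomical diagnosis plus an
intestinal marker rule (CK20 / MUC2 positivity), with small clusters left
unclassified.

A PCA-based confounder check (probe type; analyzed-marker panels) completes
the module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .core_data import ScoreMatrix

__all__ = [
    "Dendrogram",
    "TypeAssignment",
    "PcaCheck",
    "pearson_distance",
    "agglomerative_average",
    "cut_dendrogram",
    "assign_types",
    "pca_check",
]

logger = logging.getLogger(__name__)

EPB, INT, ICC, HCC, UNCLASSIFIED = "EPB", "INT", "ICC", "HCC", "unclassified"

#: Diagnosis -> type-name rule for clusters (the intestinal type cannot be
#: inferred from anatomy; it is named by the marker rule instead).
_DIAGNOSIS_TO_TYPE = {
    "ampullary": EPB,
    "pancreatic_ductal": EPB,
    "distal_bile_duct": EPB,
    "gallbladder": EPB,
    "perihilar_cc": EPB,
    "intrahepatic_cc": ICC,
    "hcc": HCC,
}


@dataclass
class Dendrogram:
    """Average-linkage merge tree.

    ``merges[i] = (a, b)`` joins clusters ``a`` and ``b`` at ``heights[i]``;
    leaves are 0..n-1 and merge i creates cluster id ``n + i`` (the usual
    linkage-matrix convention).
    """

    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,) float
    leaf_order: np.ndarray  # (n,) int
    n_leaves: int
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over n leaves must contain n-1 merges")
        if np.any(np.diff(self.heights) < -1e-10):
            logger.warning("non-monotone merge heights (linkage inversion)")

    def to_linkage_matrix(self) -> np.ndarray:
        """SciPy-style (n-1, 4) linkage matrix [a, b, height, size]."""
        n = self.n_leaves
        sizes = np.ones(2 * n - 1)
        Z = np.zeros((n - 1, 4))
        for i, ((a, b), h) in enumerate(zip(self.merges, self.heights)):
            sizes[n + i] = sizes[a] + sizes[b]
            Z[i] = [a, b, h, sizes[n + i]]
        return Z

    def to_newick(self) -> str:
        n = self.n_leaves
        names = self.sample_ids or [str(i) for i in range(n)]
        node_h = np.concatenate([np.zeros(n), self.heights])

        def rec(node: int) -> str:
            if node < n:
                return names[node]
            a, b = self.merges[node - n]
            h = node_h[node]
            return (
                f"({rec(a)}:{h - node_h[a]:.6g},{rec(b)}:{h - node_h[b]:.6g})"
            )

        return rec(2 * n - 2) + ";"


@dataclass
class TypeAssignment:
    """Per-sample tumor-type labels plus the cluster table behind them."""

    labels: pd.Series  # sample id -> type label
    clusters: pd.DataFrame  # cluster, size, dominant_diagnosis, purity, label
    k: int


@dataclass
class PcaCheck:
    coordinates: pd.DataFrame  # PC1, PC2 per sample
    silhouette: float
    admixture: bool
    explained_variance_ratio: np.ndarray


# ---------------------------------------------------------------------------


def pearson_distance(m: ScoreMatrix | pd.DataFrame) -> np.ndarray:
    """Pearson distance d = 1 - r between all pairs of sample vectors.

    Zero-variance sample vectors have no defined correlation; their r is set
    to 0 (d = 1) with a logged warning rather than propagating NaN.
    """
    scores = m.scores if isinstance(m, ScoreMatrix) else m
    X = scores.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("Pearson distance needs at least 2 markers")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing values; impute before clustering")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("%d zero-variance sample vector(s); correlation set to 0", zero.sum())
    safe = np.where(zero, 1.0, norms)
    r = (Xc @ Xc.T) / np.outer(safe, safe)
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return d


def agglomerative_average(D: np.ndarray, sample_ids: list[str] | None = None) -> Dendrogram:
    """Unweighted average-linkage (UPGMA-style) agglomeration.

    The distance between two clusters is the unweighted mean of all
    cross-pair distances; at every step the pair at minimum distance merges,
    ties broken by the smallest (a, b) cluster-id pair.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < -1e-12):
        raise ValueError("distance matrix must be non-negative")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")

    # active clusters kept in ascending id order; W is their pairwise distance
    ids = list(range(n))
    sizes = [1.0] * n
    W = D.copy().astype(float)
    merges = np.zeros((n - 1, 2), dtype=int)
    heights = np.zeros(n - 1)
    children: dict[int, tuple[int, int]] = {}

    for step in range(n - 1):
        mask = W.copy()
        mask[np.tril_indices_from(mask, k=0)] = np.inf
        flat = int(np.argmin(mask))
        pi, pj = divmod(flat, mask.shape[0])
        h = W[pi, pj]
        a, b = ids[pi], ids[pj]
        merges[step] = (a, b)
        heights[step] = h
        new_id = n + step
        children[new_id] = (a, b)
        # Lance-Williams update for unweighted average linkage
        si, sj = sizes[pi], sizes[pj]
        new_row = (si * W[pi] + sj * W[pj]) / (si + sj)
        keep = [p for p in range(len(ids)) if p not in (pi, pj)]
        W = W[np.ix_(keep, keep)]
        new_col = new_row[keep]
        W = np.pad(W, ((0, 1), (0, 1)))
        W[-1, :-1] = new_col
        W[:-1, -1] = new_col
        W[-1, -1] = 0.0
        ids = [ids[p] for p in keep] + [new_id]
        sizes = [sizes[p] for p in keep] + [si + sj]

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return leaves(a) + leaves(b)

    leaf_order = np.array(leaves(2 * n - 2), dtype=int)
    return Dendrogram(merges, heights, leaf_order, n, sample_ids=list(sample_ids or []))


def cut_dendrogram(t: Dendrogram, k: int) -> np.ndarray:
    """Cluster labels after removing the k-1 highest merges.

    Labels are integers 0..k-1 numbered by first appearance in sample
    order, making the labeling invariant to internal merge bookkeeping.
    """
    n = t.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict[int, int] = {i: i for i in range(n)}  # cluster id -> a leaf root
    for i in range(n - 1 - (k - 1)):
        a, b = t.merges[i]
        ra, rb = find(members[a]), find(members[b])
        parent[rb] = ra
        members[n + i] = ra
    # leftover internal ids still map for completeness
    roots = [find(i) for i in range(n)]
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in seen:
            seen[r] = len(seen)
        labels[i] = seen[r]
    return labels


def assign_types(
    dend: Dendrogram,
    m: ScoreMatrix,
    control_diagnosis: str = "hcc",
    k: int | None = None,
    k_max: int = 12,
    min_size: int = 5,
    purity_min: float = 0.9,
    control_capture: float = 0.9,
    positivity_threshold: float = 10.0,
    manual_labels: pd.Series | None = None,
) -> TypeAssignment:
    """Turn a dendrogram cut into immunohistochemical tumor-type labels.

    The number of clusters is the smallest k in [2, k_max] at which at
    least ``control_capture`` of the control-group samples (hepatocellular
    carcinoma by default) sit in clusters of >= ``purity_min`` control
    purity — i.e. the cut at which the well-characterized control type has
    separated.  Clusters are then named: smaller than ``min_size`` ->
    unclassified; CK20 or MUC2 positive fraction > 0.5 -> INT; otherwise by
    dominant diagnosis (hcc -> HCC, intrahepatic_cc -> ICC, the
    pancreatic/extrahepatic sites -> EPB).

    ``manual_labels`` (sample id -> type) overrides the automatic naming
    for the listed samples, mirroring expert review of the dendrogram.
    """
    diagnoses = m.meta["diagnosis"]
    if control_diagnosis not in set(diagnoses):
        raise ValueError(f"control diagnosis {control_diagnosis!r} absent from cohort")
    n = dend.n_leaves
    control = (diagnoses == control_diagnosis).to_numpy()

    def capture_at(kk: int) -> tuple[np.ndarray, float, int]:
        lab = cut_dendrogram(dend, kk)
        captured = 0
        sizes = np.bincount(lab)
        for c in np.unique(lab):
            in_c = lab == c
            purity = control[in_c].mean()
            if purity >= purity_min:
                captured += int((in_c & control).sum())
        return lab, captured / control.sum(), int((sizes >= min_size).sum())

    if k is None:
        # smallest cut that both isolates the control group and yields at
        # least four substantive clusters (one per candidate tumor type)
        need_big = 4 if n >= 4 * min_size else 2
        chosen, labels_int = None, None
        for kk in range(2, min(k_max, n) + 1):
            lab, frac, n_big = capture_at(kk)
            if frac >= control_capture and n_big >= need_big:
                chosen, labels_int = kk, lab
                break
        if chosen is None:
            warnings.warn(
                f"no cut up to k_max={k_max} isolates the control group; using k_max"
            )
            chosen = min(k_max, n)
            labels_int = cut_dendrogram(dend, chosen)
    else:
        chosen = k
        labels_int = cut_dendrogram(dend, k)

    scores = m.scores
    rows = []
    type_labels = pd.Series(index=m.scores.index, dtype=object, name="ihc_type")
    for c in np.unique(labels_int):
        in_c = labels_int == c
        sub_diag = diagnoses[in_c]
        dominant = sub_diag.mode().iloc[0]
        purity = float((sub_diag == dominant).mean())
        size = int(in_c.sum())
        if size < min_size:
            label = UNCLASSIFIED
        else:
            label = None
            for marker in ("CK20", "MUC2"):
                if marker in scores.columns:
                    sub = scores.loc[in_c, marker].dropna()
                    if len(sub) and (sub > positivity_threshold).mean() > 0.5:
                        label = INT
                        break
            if label is None:
                label = _DIAGNOSIS_TO_TYPE.get(dominant, EPB)
        rows.append((int(c), size, dominant, purity, label))
        type_labels[in_c] = label
    if manual_labels is not None:
        for sid, lab in manual_labels.items():
            type_labels[sid] = lab
    clusters = pd.DataFrame(
        rows, columns=["cluster", "size", "dominant_diagnosis", "purity", "label"]
    )
    return TypeAssignment(labels=type_labels, clusters=clusters, k=chosen)


def pca_check(
    data: ScoreMatrix | pd.DataFrame,
    grouping: pd.Series | np.ndarray,
    admixture_threshold: float = 0.1,
) -> PcaCheck:
    """PCA confounder check: do the groups separate on the first two PCs?

    ``data`` is either a (complete) score matrix or any numeric frame —
    e.g. the 0/1 analyzed-marker mask, to test whether marker-panel choice
    drives structure.  The separation statistic is the mean silhouette of
    ``grouping`` on PC1/PC2; silhouettes below ``admixture_threshold``
    declare an admixture (no confounding).
    """
    X = (data.scores if isinstance(data, ScoreMatrix) else data).to_numpy(dtype=float)
    index = (data.scores if isinstance(data, ScoreMatrix) else data).index
    if X.shape[0] < 3:
        raise ValueError("PCA check needs at least 3 samples")
    if np.allclose(X, X[0]):
        raise ValueError("constant matrix: PCA undefined")
    groups = np.asarray(grouping)
    if len(np.unique(groups)) < 2:
        raise ValueError("separation statistic undefined for a single group")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    sil = float(silhouette_score(coords, groups))
    return PcaCheck(
        coordinates=pd.DataFrame(coords, index=index, columns=["PC1", "PC2"]),
        silhouette=sil,
        admixture=sil < admixture_threshold,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
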