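"""Missing-score imputation.

Two strategies, used for different purposes downstream:

* :func:`knn_impute` — k-nearest-neighbor imputation over *samples*; this
  completes the matrix once for the main cluster / differential-expression
  analysis.
* :func:`random_impute` — per-marker empirical resampling of observed
  scores; drawn fresh in every iteration of the consensus co-clustering
  network so that cluster structure is never an artifact of one particular
  completion of the data.

Neighbors are samples rather than markers: with only a few dozen antibodies
marker-space neighborhoods are unstable, whereas hundreds of tumor samples
give each missing cell a meaningful donor pool.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import ScoreMatrix, ScoreMatrixError

__all__ = ["knn_impute", "random_impute", "pairwise_sample_distances"]


def pairwise_sample_distances(scores: pd.DataFrame) -> np.ndarray:
    """Normalized Euclidean distance between samples over co-observed markers.

    d(i,j) = sqrt( sum_{g co-observed} (x_ig - x_jg)^2 / n_co(i,j) ).
    Pairs with no co-observed marker get +inf.  Normalizing by the
    co-observed count keeps samples with few shared markers from looking
    artificially close or far.
    """
    X = scores.to_numpy(dtype=float)
    M = np.isfinite(X)
    X0 = np.where(M, X, 0.0)
    Mf = M.astype(float)
    # sum over co-observed of (x_i - x_j)^2, via the usual expansion
    sq = X0**2
    cross = X0 @ X0.T
    s = (sq @ Mf.T) + (Mf @ sq.T) - 2.0 * cross
    counts = Mf @ Mf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(np.maximum(s, 0.0) / counts)
    d[counts == 0] = np.inf
    np.fill_diagonal(d, 0.0)
    return d


def knn_impute(m: ScoreMatrix, k: int = 10) -> ScoreMatrix:
    """Complete the matrix by k-nearest-neighbor imputation over samples.

    For each missing cell (sample s, marker g) the k samples nearest to s
    (normalized Euclidean distance over co-observed markers) among those
    with g observed donate their g scores; the imputed value is their
    inverse-distance-weighted mean, clipped to [0, 100].  A zero-distance
    neighbor is copied exactly.  When no eligible neighbor exists the
    marker's observed mean is used as a fallback.  Observed cells are never
    altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = m.scores.copy()
    X = scores.to_numpy(dtype=float)
    observed = np.isfinite(X)
    if observed.all():
        return m.copy()
    no_obs = ~observed.any(axis=0)
    if no_obs.any():
        names = [m.marker_names[j] for j in np.where(no_obs)[0]]
        raise ScoreMatrixError(f"cannot impute: marker(s) with zero observed values: {names}")
    n_shared = (observed.astype(float) @ observed.astype(float).T) - np.diag(
        observed.sum(axis=1).astype(float)
    )
    if (n_shared.max(axis=1) < 1).any():
        raise ScoreMatrixError("a sample shares no observed marker with any other sample")

    D = pairwise_sample_distances(scores)
    col_means = np.nanmean(X, axis=0)
    eps = 1e-9
    out = X.copy()
    for i in range(X.shape[0]):
        miss = np.where(~observed[i])[0]
        if miss.size == 0:
            continue
        for j in miss:
            eligible = np.where(observed[:, j] & np.isfinite(D[i]))[0]
            eligible = eligible[eligible != i]
            if eligible.size == 0:
                out[i, j] = col_means[j]
                continue
            order = eligible[np.argsort(D[i, eligible], kind="stable")][:k]
            d = D[i, order]
            if np.any(d == 0):
                out[i, j] = X[order[d == 0][0], j]
            else:
                w = 1.0 / (d + eps)
                out[i, j] = float(np.dot(w, X[order, j]) / w.sum())
    out = np.clip(out, 0.0, 100.0)
    out[observed] = X[observed]
    return ScoreMatrix(
        pd.DataFrame(out, index=scores.index, columns=scores.columns), m.meta.copy()
    )


def random_impute(
    m: ScoreMatrix,
    rng: np.random.Generator | int | None = None,
    uniform: bool = False,
) -> ScoreMatrix:
    """Fill missing cells with random values.

    By default each missing cell is drawn from the empirical distribution of
    that marker's observed scores, which preserves every marker's score
    distribution; ``uniform=True`` draws from Uniform[0, 100] instead.
    Observed cells are unchanged; output is deterministic for a given
    generator state.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = m.scores.to_numpy(dtype=float).copy()
    observed = np.isfinite(X)
    for j in range(X.shape[1]):
        miss = ~observed[:, j]
        if not miss.any():
            continue
        if uniform:
            X[miss, j] = rng.uniform(0, 100, size=miss.sum())
        else:
            donors = X[observed[:, j], j]
            if donors.size == 0:
                raise ScoreMatrixError(
                    f"cannot impute: marker {m.marker_names[j]!r} has zero observed values"
                )
            X[miss, j] = rng.choice(donors, size=miss.sum(), replace=True)
    return ScoreMatrix(
        pd.DataFrame(X, index=m.scores.index, columns=m.scores.columns), m.meta.copy()
    )
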