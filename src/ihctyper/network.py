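"""Consensus co-clustering network.

Instead of committing to one imputation of the missing scores, the matrix
is completed many times with random values drawn from each marker's
observed score distribution; each completion is clustered (Pearson
distance, average linkage, cut at k) and the fraction of iterations in
which two samples share a cluster is accumulated into a co-membership
matrix.  Thresholding that matrix yields a weighted sample graph whose
structure is robust to the missing-data pattern.  Layout is left to
external viewers (e.g. Gephi); this module only builds and exports the
graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core_data import ScoreMatrix
from .cluster import agglomerative_average, cut_dendrogram, pearson_distance
from .impute import random_impute

__all__ = ["ComembershipMatrix", "comembership", "build_graph", "write_graph"]


@dataclass
class ComembershipMatrix:
    """Samples x samples co-clustering frequencies."""

    values: pd.DataFrame
    n_iterations: int
    k: int

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T):
            raise ValueError("co-membership matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("co-membership diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("co-membership entries must lie in [0,1]")


def _single_run_comembership(m: ScoreMatrix, k: int) -> np.ndarray:
    D = pearson_distance(m)
    dend = agglomerative_average(D)
    labels = cut_dendrogram(dend, k)
    return (labels[:, None] == labels[None, :]).astype(float)


def comembership(
    m: ScoreMatrix,
    k: int,
    n_iter: int = 200,
    seed: int = 0,
    uniform: bool = False,
) -> ComembershipMatrix:
    """Mean co-clustering indicator over random-imputation iterations.

    Each iteration draws a fresh random completion of the missing cells,
    clusters it, and marks sample pairs sharing a cluster at cut k.  A
    complete matrix needs no imputation, so every iteration is identical
    and the result equals the single deterministic run with entries in
    {0, 1}.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > m.n_samples:
        raise ValueError(f"k={k} exceeds the number of samples ({m.n_samples})")
    if m.is_complete:
        C = _single_run_comembership(m, k)
        return ComembershipMatrix(
            pd.DataFrame(C, index=m.scores.index, columns=m.scores.index), n_iter, k
        )
    rng = np.random.default_rng(seed)
    acc = np.zeros((m.n_samples, m.n_samples))
    for _ in range(n_iter):
        completed = random_impute(m, rng=rng, uniform=uniform)
        acc += _single_run_comembership(completed, k)
    acc /= n_iter
    np.fill_diagonal(acc, 1.0)
    return ComembershipMatrix(
        pd.DataFrame(acc, index=m.scores.index, columns=m.scores.index), n_iter, k
    )


def build_graph(
    C: ComembershipMatrix,
    edge_threshold: float = 0.5,
    attrs: pd.DataFrame | None = None,
) -> nx.Graph:
    """Weighted undirected sample graph from a co-membership matrix.

    Nodes are samples (with any per-sample attributes supplied: type,
    diagnosis, probe, marker scores for profile coloring); an edge joins
    samples whose co-clustering frequency is at least ``edge_threshold``,
    weighted by that frequency.  Self-edges are excluded.
    """
    if not (0 < edge_threshold <= 1):
        raise ValueError("edge_threshold must be in (0,1]")
    g = nx.Graph()
    samples = list(C.values.index)
    for s in samples:
        node_attrs = {}
        if attrs is not None and s in attrs.index:
            for key, val in attrs.loc[s].items():
                if pd.isna(val):
                    continue
                if isinstance(val, (np.integer,)):
                    val = int(val)
                elif isinstance(val, (np.floating,)):
                    val = float(val)
                elif isinstance(val, (np.bool_, bool)):
                    val = bool(val)
                else:
                    val = str(val)
                node_attrs[str(key)] = val
        g.add_node(s, **node_attrs)
    V = C.values.to_numpy()
    for i, si in enumerate(samples):
        for j in range(i + 1, len(samples)):
            if V[i, j] >= edge_threshold:
                g.add_edge(si, samples[j], weight=float(V[i, j]))
    return g


def write_graph(g: nx.Graph, path: str | Path) -> None:
    """Export as GEXF, GraphML, or edge-list CSV by file extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".gexf":
        nx.write_gexf(g, path)
    elif suffix == ".graphml":
        nx.write_graphml(g, path)
    elif suffix == ".csv":
        rows = [(u, v, d.get("weight", 1.0)) for u, v, d in g.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported graph format: {suffix}")
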