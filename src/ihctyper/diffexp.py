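"""Permutation-based discriminant-marker testing between tumor types.

Three non-parametric two-group tests are run per marker and a marker is
declared *consensus-significant* only when all three agree — the rule used
to minimize false positives when defining the discriminant panels:

* rank product — for every cross-group sample pair, markers are ranked by
  score difference; the statistic is the geometric mean of a marker's ranks
  over all pairs (differences, not ratios: IHC percentages contain zeros).
* SAM-style moderated mean difference — d = (mean_A - mean_B) / (s + s0)
  with the fudge factor s0 set to the median per-marker standard error.
* Westfall-Young maxT — Welch t statistics with step-down permutation
  adjustment controlling the family-wise error rate.

All three share one label-permutation engine; when the number of distinct
group assignments is small the null is enumerated exhaustively, giving
exact permutation p-values, otherwise assignments are sampled and the
add-one-corrected estimate (b+1)/(B+1) is reported.

The module also computes positivity profiles (the immunohistogram data):
per type and marker, the fraction of samples with immunoreactivity in more
than 10% of tumor cells.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .core_data import ScoreMatrix, positivity_fractions

__all__ = [
    "MethodResult",
    "ConsensusResult",
    "PositivityProfile",
    "rank_product_test",
    "sam_test",
    "maxt_test",
    "consensus_markers",
    "positivity_profiles",
    "run_pairwise",
    "DEFAULT_PAIRS",
]

#: The clinically most relevant pairwise differential diagnoses.
DEFAULT_PAIRS = (("EPB", "INT"), ("EPB", "ICC"), ("ICC", "HCC"))

MAX_EXHAUSTIVE = 20_000


@dataclass
class MethodResult:
    method: str  # rank_product | sam | maxt
    table: pd.DataFrame  # index markers: statistic, p_raw, p_adj, direction
    n_null: int  # permutations (or enumerated assignments) behind the p-values
    exhaustive: bool
    comparison: tuple[str, str] | None = None

    def significant(self, alpha: float = 0.05) -> list[str]:
        return list(self.table.index[self.table["p_adj"] <= alpha])


@dataclass
class ConsensusResult:
    comparison: tuple[str, str]
    table: pd.DataFrame  # rank_product_p, sam_p, maxt_p, direction, consensus

    @property
    def consensus_markers(self) -> list[str]:
        return list(self.table.index[self.table["consensus"]])


@dataclass
class PositivityProfile:
    fractions: pd.DataFrame  # markers x types, NaN when n = 0
    counts: pd.DataFrame  # observed sample counts, markers x types
    threshold: float


# ---------------------------------------------------------------------------
# permutation engine


def _as_matrix(A) -> pd.DataFrame:
    return A if isinstance(A, pd.DataFrame) else pd.DataFrame(np.asarray(A, dtype=float))


def _check_groups(A: pd.DataFrame, B: pd.DataFrame) -> None:
    if list(A.columns) != list(B.columns):
        raise ValueError("groups must share an identical marker set")
    if A.shape[1] == 0:
        raise ValueError("zero markers")
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs at least 2 samples")
    if A.isna().any().any() or B.isna().any().any():
        raise ValueError("groups contain missing values; impute first")


def _null_assignments(n: int, n_a: int, n_perm: int, seed: int):
    """Group-A index sets for the permutation null.

    Exhaustive enumeration of all C(n, n_a) assignments when that count is
    at most MAX_EXHAUSTIVE (the observed labeling is one of them);
    otherwise ``n_perm`` sampled shuffles.
    """
    if comb(n, n_a) <= MAX_EXHAUSTIVE:
        sets = [np.array(c, dtype=int) for c in itertools.combinations(range(n), n_a)]
        return sets, True
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    sets = []
    for _ in range(n_perm):
        rng.shuffle(idx)
        sets.append(np.sort(idx[:n_a]).copy())
    return sets, False


def _perm_pvalue(null_counts: np.ndarray, n_null: int, exhaustive: bool) -> np.ndarray:
    """Permutation p from exceedance counts (observed excluded from counts)."""
    if exhaustive:
        # the enumeration includes the observed assignment
        return null_counts / n_null
    return (null_counts + 1) / (n_null + 1)


# ---------------------------------------------------------------------------
# rank product


def _rank_product(X: np.ndarray, ia: np.ndarray, ib: np.ndarray):
    """(RP_up, RP_down): geometric-mean ranks over all cross-group pairs.

    Within each cross pair markers are ranked by score difference with
    mid-ranks for ties; rank 1 means the largest difference (up) or the
    smallest (down).
    """
    diffs = X[ia][:, None, :] - X[ib][None, :, :]  # (nA, nB, G)
    diffs = diffs.reshape(-1, X.shape[1])
    r_up = rankdata(-diffs, axis=1)
    log_up = np.log(r_up).mean(axis=0)
    g = X.shape[1]
    # descending and ascending mid-ranks sum to G+1 pairwise
    r_down = (g + 1) - r_up
    log_down = np.log(r_down).mean(axis=0)
    return np.exp(log_up), np.exp(log_down)


def rank_product_test(
    A, B, n_perm: int = 1000, seed: int = 0, comparison=None
) -> MethodResult:
    """Two-sided rank-product test on score differences.

    The reported statistic is min(RP_up, RP_down); its permutation p-value
    is two-sided by construction (small RP on either side is extreme).
    Benjamini-Hochberg adjustment across markers.
    """
    A, B = _as_matrix(A), _as_matrix(B)
    _check_groups(A, B)
    X = np.vstack([A.to_numpy(float), B.to_numpy(float)])
    n, n_a = X.shape[0], len(A)
    all_idx = np.arange(n)

    obs_up, obs_down = _rank_product(X, all_idx[:n_a], all_idx[n_a:])
    obs = np.minimum(obs_up, obs_down)

    sets, exhaustive = _null_assignments(n, n_a, n_perm, seed)
    counts = np.zeros(X.shape[1])
    counts_up = np.zeros(X.shape[1])
    counts_down = np.zeros(X.shape[1])
    for ia in sets:
        ib = np.setdiff1d(all_idx, ia, assume_unique=True)
        up, down = _rank_product(X, ia, ib)
        counts += np.minimum(up, down) <= obs + 1e-12
        counts_up += up <= obs_up + 1e-12
        counts_down += down <= obs_down + 1e-12
    p_raw = _perm_pvalue(counts, len(sets), exhaustive)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "statistic": obs,
            "p_up": _perm_pvalue(counts_up, len(sets), exhaustive),
            "p_down": _perm_pvalue(counts_down, len(sets), exhaustive),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.where(obs_up <= obs_down, "up", "down"),
        },
        index=A.columns,
    )
    return MethodResult("rank_product", table, len(sets), exhaustive, comparison)


# ---------------------------------------------------------------------------
# SAM-style moderated difference


def _sam_d(X: np.ndarray, ia: np.ndarray, ib: np.ndarray, s0: float) -> np.ndarray:
    a, b = X[ia], X[ib]
    na, nb = len(ia), len(ib)
    num = a.mean(axis=0) - b.mean(axis=0)
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (
        na + nb - 2
    )
    s = np.sqrt(sp2 * (1 / na + 1 / nb))
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, num / denom, np.where(num == 0, 0.0, np.sign(num) * np.inf))
    return d


def _sam_s0(X: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> float:
    a, b = X[ia], X[ib]
    na, nb = len(ia), len(ib)
    sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (
        na + nb - 2
    )
    return float(np.median(np.sqrt(sp2 * (1 / na + 1 / nb))))


def sam_test(A, B, n_perm: int = 1000, seed: int = 0, comparison=None) -> MethodResult:
    """SAM-style moderated mean-difference test.

    d = (mean_A - mean_B) / (s + s0) with s the pooled standard error and
    the stabilizer s0 fixed at the median of the per-marker standard errors
    (computed once on the observed grouping and held fixed across
    permutations).  p-values from the permutation null of |d|;
    Benjamini-Hochberg adjustment.
    """
    A, B = _as_matrix(A), _as_matrix(B)
    _check_groups(A, B)
    X = np.vstack([A.to_numpy(float), B.to_numpy(float)])
    n, n_a = X.shape[0], len(A)
    all_idx = np.arange(n)
    s0 = _sam_s0(X, all_idx[:n_a], all_idx[n_a:])
    obs = _sam_d(X, all_idx[:n_a], all_idx[n_a:], s0)

    sets, exhaustive = _null_assignments(n, n_a, n_perm, seed)
    counts = np.zeros(X.shape[1])
    counts_up = np.zeros(X.shape[1])
    counts_down = np.zeros(X.shape[1])
    for ia in sets:
        ib = np.setdiff1d(all_idx, ia, assume_unique=True)
        d = _sam_d(X, ia, ib, s0)
        counts += np.abs(d) >= np.abs(obs) - 1e-12
        counts_up += d >= obs - 1e-12
        counts_down += d <= obs + 1e-12
    p_raw = _perm_pvalue(counts, len(sets), exhaustive)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "statistic": obs,
            "p_up": _perm_pvalue(counts_up, len(sets), exhaustive),
            "p_down": _perm_pvalue(counts_down, len(sets), exhaustive),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.where(obs >= 0, "up", "down"),
        },
        index=A.columns,
    )
    return MethodResult("sam", table, len(sets), exhaustive, comparison)


# ---------------------------------------------------------------------------
# Westfall-Young maxT


def _welch_t(X: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    a, b = X[ia], X[ib]
    num = a.mean(axis=0) - b.mean(axis=0)
    denom = np.sqrt(a.var(axis=0, ddof=1) / len(ia) + b.var(axis=0, ddof=1) / len(ib))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, num / denom, np.where(num == 0, 0.0, np.sign(num) * np.inf))
    return t


def maxt_test(A, B, n_perm: int = 1000, seed: int = 0, comparison=None) -> MethodResult:
    """Westfall-Young step-down maxT adjustment of Welch t statistics.

    Markers are ordered by decreasing |t|; for marker j the adjusted p is
    the exceedance probability of the successive maximum of permuted |t|
    over markers ranked j and below, with monotonicity enforced down the
    ordering.  This controls the family-wise error rate, so no further
    adjustment is applied.
    """
    A, B = _as_matrix(A), _as_matrix(B)
    _check_groups(A, B)
    X = np.vstack([A.to_numpy(float), B.to_numpy(float)])
    n, n_a = X.shape[0], len(A)
    all_idx = np.arange(n)
    obs = _welch_t(X, all_idx[:n_a], all_idx[n_a:])
    abs_obs = np.abs(obs)
    order = np.argsort(-abs_obs, kind="stable")  # most significant first

    sets, exhaustive = _null_assignments(n, n_a, n_perm, seed)
    g = X.shape[1]
    raw_counts = np.zeros(g)
    up_counts = np.zeros(g)
    down_counts = np.zeros(g)
    step_counts = np.zeros(g)
    for ia in sets:
        ib = np.setdiff1d(all_idx, ia, assume_unique=True)
        t = _welch_t(X, ia, ib)
        at = np.abs(t)
        raw_counts += at >= abs_obs - 1e-12
        up_counts += t >= obs - 1e-12
        down_counts += t <= obs + 1e-12
        # successive maxima from the least significant marker upward
        succ = np.maximum.accumulate(at[order][::-1])[::-1]
        step_counts[order] += succ >= abs_obs[order] - 1e-12
    p_raw = _perm_pvalue(raw_counts, len(sets), exhaustive)
    p_step = _perm_pvalue(step_counts, len(sets), exhaustive)
    # enforce monotone non-decreasing adjusted p along the significance order
    p_adj = np.empty(g)
    p_adj[order] = np.maximum.accumulate(p_step[order])
    table = pd.DataFrame(
        {
            "statistic": obs,
            "p_up": _perm_pvalue(up_counts, len(sets), exhaustive),
            "p_down": _perm_pvalue(down_counts, len(sets), exhaustive),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.where(obs >= 0, "up", "down"),
        },
        index=A.columns,
    )
    return MethodResult("maxt", table, len(sets), exhaustive, comparison)


# ---------------------------------------------------------------------------
# consensus and profiles


def consensus_markers(
    r1: MethodResult, r2: MethodResult, r3: MethodResult, alpha: float = 0.05
) -> ConsensusResult:
    """All-three consensus rule.

    A marker is consensus-significant only when each method's adjusted p is
    at or below alpha *and* the three directions agree.
    """
    results = {r.method: r for r in (r1, r2, r3)}
    if set(results) != {"rank_product", "sam", "maxt"}:
        raise ValueError("need one result from each of rank_product, sam, maxt")
    markers = list(r1.table.index)
    for r in (r2, r3):
        if list(r.table.index) != markers:
            raise ValueError("marker set mismatch between method results")
    comps = {r.comparison for r in (r1, r2, r3)}
    if len(comps) != 1:
        raise ValueError("method results come from different comparisons")
    rp, sam, mt = results["rank_product"], results["sam"], results["maxt"]
    sig = (
        (rp.table["p_adj"] <= alpha)
        & (sam.table["p_adj"] <= alpha)
        & (mt.table["p_adj"] <= alpha)
    )
    agree = (rp.table["direction"] == sam.table["direction"]) & (
        sam.table["direction"] == mt.table["direction"]
    )
    table = pd.DataFrame(
        {
            "rank_product_p": rp.table["p_adj"],
            "sam_p": sam.table["p_adj"],
            "maxt_p": mt.table["p_adj"],
            "direction": sam.table["direction"],
            "consensus": (sig & agree).astype(bool),
        },
        index=pd.Index(markers, name="marker"),
    )
    return ConsensusResult(comparison=r1.comparison, table=table)


def positivity_profiles(
    m: ScoreMatrix,
    assignment: pd.Series,
    threshold: float = 10.0,
) -> PositivityProfile:
    """Per-type, per-marker positive fractions (the immunohistogram data).

    Positivity is immunoreactivity in strictly more than ``threshold``
    percent of tumor cells; only observed scores enter the denominator.
    Samples labeled ``unclassified`` are excluded.  Type/marker cells with
    no observed score are reported as NaN with n = 0.
    """
    assignment = assignment.reindex(m.scores.index)
    types = [t for t in pd.unique(assignment.dropna()) if t != "unclassified"]
    if not types:
        raise ValueError("no classified types in assignment")
    frac = pd.DataFrame(index=m.marker_names, columns=types, dtype=float)
    counts = pd.DataFrame(0, index=m.marker_names, columns=types, dtype=int)
    for t in types:
        sub = m.scores.loc[(assignment == t).to_numpy()]
        if sub.empty:
            raise ValueError(f"empty type {t!r}")
        f, n = positivity_fractions(sub, threshold)
        frac[t] = f
        counts[t] = n
    return PositivityProfile(fractions=frac, counts=counts, threshold=threshold)


def run_pairwise(
    m: ScoreMatrix,
    assignment: pd.Series,
    pairs=DEFAULT_PAIRS,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[tuple[str, str], ConsensusResult]:
    """Run all three tests plus the consensus rule for each type pair."""
    out = {}
    assignment = assignment.reindex(m.scores.index)
    for i, (ta, tb) in enumerate(pairs):
        A = m.scores.loc[(assignment == ta).to_numpy()]
        B = m.scores.loc[(assignment == tb).to_numpy()]
        comp = (ta, tb)
        r1 = rank_product_test(A, B, n_perm=n_perm, seed=seed + 3 * i, comparison=comp)
        r2 = sam_test(A, B, n_perm=n_perm, seed=seed + 3 * i + 1, comparison=comp)
        r3 = maxt_test(A, B, n_perm=n_perm, seed=seed + 3 * i + 2, comparison=comp)
        out[comp] = consensus_markers(r1, r2, r3, alpha=alpha)
    return out
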