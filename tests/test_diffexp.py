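import itertools

import numpy as np
import pandas as pd
import pytest

from ihctyper.diffexp import (
    consensus_markers,
    maxt_test,
    positivity_profiles,
    rank_product_test,
    sam_test,
)
from ihctyper.synthetic import CohortSpec, generate_cohort

from conftest import make_matrix


# --- independent exhaustive oracles (brute force, per definition) ----------


def oracle_rank_product_p(X, n_a):
    """Exhaustive two-sided rank-product p per marker, straight from the
    definition: enumerate every group assignment, compute geometric-mean
    ranks of score differences over all cross pairs, count assignments with
    min(RP_up, RP_down) at or below the observed."""
    from scipy.stats import rankdata

    n, g = X.shape

    def rp(ia):
        ib = [i for i in range(n) if i not in ia]
        stats = []
        for direction in (-1, 1):
            logs = np.zeros(g)
            count = 0
            for a in ia:
                for b in ib:
                    ranks = rankdata(direction * (X[a] - X[b]))
                    # direction=-1: rank 1 = largest difference
                    logs += np.log(ranks)
                    count += 1
            stats.append(np.exp(logs / count))
        return np.minimum(stats[0], stats[1])

    obs = rp(tuple(range(n_a)))
    assignments = list(itertools.combinations(range(n), n_a))
    counts = np.zeros(g)
    for ia in assignments:
        counts += rp(ia) <= obs + 1e-12
    return counts / len(assignments)


def oracle_abs_stat_p(X, n_a, stat):
    """Exhaustive permutation p of |stat| for any statistic function."""
    n, g = X.shape
    obs = np.abs(stat(X, tuple(range(n_a))))
    assignments = list(itertools.combinations(range(n), n_a))
    counts = np.zeros(g)
    for ia in assignments:
        counts += np.abs(stat(X, ia)) >= obs - 1e-12
    return counts / len(assignments)


def welch(X, ia):
    ib = [i for i in range(X.shape[0]) if i not in ia]
    a, b = X[list(ia)], X[ib]
    num = a.mean(0) - b.mean(0)
    den = np.sqrt(a.var(0, ddof=1) / len(a) + b.var(0, ddof=1) / len(b))
    return num / den


class TestRankProduct:
    def test_dominant_marker_gets_rank_one_everywhere(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(40, 60, (4, 6))
        B = rng.uniform(40, 60, (4, 6))
        A[:, 0] += 100  # marker 0 has the largest difference in every pair
        r = rank_product_test(pd.DataFrame(A), pd.DataFrame(B), seed=1)
        assert r.table["statistic"].iloc[0] == pytest.approx(1.0)
        assert r.table["p_raw"].iloc[0] == r.table["p_raw"].min()
        assert r.table["direction"].iloc[0] == "up"

    def test_exhaustive_p_equals_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.uniform(0, 100, (6, 5))
        r = rank_product_test(pd.DataFrame(X[:3]), pd.DataFrame(X[3:]), seed=0)
        assert r.exhaustive and r.n_null == 20
        np.testing.assert_allclose(
            r.table["p_raw"].to_numpy(), oracle_rank_product_p(X, 3)
        )

    def test_requires_two_samples_per_group(self):
        with pytest.raises(ValueError):
            rank_product_test(pd.DataFrame([[1.0, 2]]), pd.DataFrame([[3.0, 4]] * 3))


class TestSam:
    def test_equal_group_means_give_zero_statistic(self):
        A = pd.DataFrame([[10.0, 50], [20, 60], [30, 40]])
        B = pd.DataFrame([[15.0, 10], [25, 20], [20, 30]])
        r = sam_test(A, B, seed=0)
        assert r.table["statistic"].iloc[0] == pytest.approx(0.0)

    def test_large_s0_limit_ranks_by_mean_difference(self):
        from ihctyper import diffexp as dx

        rng = np.random.default_rng(1)
        X = rng.uniform(0, 100, (8, 6))
        ia, ib = np.arange(4), np.arange(4, 8)
        d = dx._sam_d(X, ia, ib, s0=1e9)
        mean_diff = X[:4].mean(0) - X[4:].mean(0)
        assert list(np.argsort(np.abs(d))) == list(np.argsort(np.abs(mean_diff)))

    def test_exhaustive_p_equals_enumeration_oracle(self):
        from ihctyper.diffexp import _sam_d, _sam_s0

        rng = np.random.default_rng(7)
        X = rng.uniform(0, 100, (6, 5))
        r = sam_test(pd.DataFrame(X[:3]), pd.DataFrame(X[3:]), seed=0)
        s0 = _sam_s0(X, np.arange(3), np.arange(3, 6))
        oracle = oracle_abs_stat_p(
            X, 3, lambda Y, ia: _sam_d(
                Y, np.array(ia), np.array([i for i in range(6) if i not in ia]), s0
            )
        )
        np.testing.assert_allclose(r.table["p_raw"].to_numpy(), oracle)

    def test_planted_shift_detected(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            A = rng.normal(50, 15, (10, 8)).clip(0, 100)
            B = rng.normal(50, 15, (10, 8)).clip(0, 100)
            A[:, 0] = rng.normal(90, 15, 10).clip(0, 100)  # ~40-unit shift
            r = sam_test(pd.DataFrame(A), pd.DataFrame(B), n_perm=500, seed=seed)
            hits += r.table["p_adj"].iloc[0] <= 0.05
        assert hits >= 0.9 * n_seeds


class TestMaxT:
    def test_single_marker_adjusted_equals_raw(self):
        rng = np.random.default_rng(3)
        A = pd.DataFrame(rng.normal(60, 10, (4, 1)))
        B = pd.DataFrame(rng.normal(40, 10, (4, 1)))
        r = maxt_test(A, B, seed=0)
        assert r.table["p_adj"].iloc[0] == pytest.approx(r.table["p_raw"].iloc[0])

    def test_adjusted_dominates_raw(self):
        rng = np.random.default_rng(4)
        A = pd.DataFrame(rng.uniform(0, 100, (5, 12)))
        B = pd.DataFrame(rng.uniform(0, 100, (5, 12)))
        r = maxt_test(A, B, n_perm=300, seed=0)
        assert (r.table["p_adj"] >= r.table["p_raw"] - 1e-12).all()

    def test_exhaustive_raw_p_equals_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 100, (6, 4))
        r = maxt_test(pd.DataFrame(X[:3]), pd.DataFrame(X[3:]), seed=0)
        np.testing.assert_allclose(
            r.table["p_raw"].to_numpy(), oracle_abs_stat_p(X, 3, welch)
        )

    def test_family_wise_error_rate_calibrated_under_global_null(self):
        """Step-down maxT holds the FWER at its nominal 5% level: with 20
        null markers, some adjusted p falls below 0.05 in ~5% of datasets
        (exhaustive 6v6 enumeration keeps each p-value exact)."""
        rng = np.random.default_rng(88)
        n_rep, fw_hits = 500, 0
        for rep in range(n_rep):
            X = rng.normal(50, 10, (12, 20))
            r = maxt_test(pd.DataFrame(X[:6]), pd.DataFrame(X[6:]), seed=rep)
            assert r.exhaustive
            fw_hits += int((r.table["p_adj"] <= 0.05).any())
        assert 0.03 <= fw_hits / n_rep <= 0.07, fw_hits / n_rep


class TestSharedProperties:
    @pytest.mark.parametrize("test", [rank_product_test, sam_test, maxt_test])
    def test_deterministic_under_seed(self, test):
        rng = np.random.default_rng(5)
        A = pd.DataFrame(rng.uniform(0, 100, (12, 6)))
        B = pd.DataFrame(rng.uniform(0, 100, (12, 6)))
        r1 = test(A, B, n_perm=200, seed=9)
        r2 = test(A, B, n_perm=200, seed=9)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert not r1.exhaustive  # C(24,12) is far beyond enumeration

    @pytest.mark.parametrize("test", [rank_product_test, sam_test, maxt_test])
    def test_shift_equivariance_of_rankings(self, test):
        rng = np.random.default_rng(6)
        A = pd.DataFrame(rng.uniform(10, 60, (5, 7)))
        B = pd.DataFrame(rng.uniform(10, 60, (5, 7)))
        r0 = test(A, B, n_perm=100, seed=2)
        r1 = test(A + 30, B + 30, n_perm=100, seed=2)
        pd.testing.assert_series_equal(r0.table["p_raw"], r1.table["p_raw"])


class TestConsensus:
    def _results(self, seed=0, n=6, g=5):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 100, (n, g))
        A, B = pd.DataFrame(X[: n // 2]), pd.DataFrame(X[n // 2 :])
        comp = ("EPB", "INT")
        return (
            rank_product_test(A, B, seed=1, comparison=comp),
            sam_test(A, B, seed=2, comparison=comp),
            maxt_test(A, B, seed=3, comparison=comp),
        )

    def test_two_of_three_is_excluded(self):
        r1, r2, r3 = self._results()
        r1.table["p_adj"] = 0.01
        r2.table["p_adj"] = 0.01
        r3.table["p_adj"] = 0.50  # maxt not significant
        r1.table["direction"] = r2.table["direction"] = r3.table["direction"] = "up"
        c = consensus_markers(r1, r2, r3, alpha=0.05)
        assert not c.table["consensus"].any()

    def test_direction_disagreement_is_excluded(self):
        r1, r2, r3 = self._results()
        for r in (r1, r2, r3):
            r.table["p_adj"] = 0.01
        r1.table["direction"] = "up"
        r2.table["direction"] = "up"
        r3.table["direction"] = "down"
        c = consensus_markers(r1, r2, r3)
        assert not c.table["consensus"].any()

    def test_consensus_is_intersection_of_significant_sets(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 100, (10, 8))
            X[:5, :2] += 60  # two genuinely shifted markers
            A, B = pd.DataFrame(X[:5]), pd.DataFrame(X[5:])
            comp = ("EPB", "ICC")
            rs = (
                rank_product_test(A, B, n_perm=200, seed=1, comparison=comp),
                sam_test(A, B, n_perm=200, seed=2, comparison=comp),
                maxt_test(A, B, n_perm=200, seed=3, comparison=comp),
            )
            c = consensus_markers(*rs, alpha=0.05)
            cset = set(c.consensus_markers)
            for r in rs:
                assert cset <= set(r.significant(0.05))

    def test_marker_mismatch_rejected(self):
        r1, r2, r3 = self._results()
        r3.table.index = [f"x{i}" for i in range(len(r3.table))]
        with pytest.raises(ValueError, match="marker set"):
            consensus_markers(r1, r2, r3)


class TestPositivityProfiles:
    def test_all_positive_scores_give_fraction_one(self):
        m = make_matrix(np.full((4, 3), 100.0))
        a = pd.Series(["EPB"] * 4, index=m.scores.index)
        prof = positivity_profiles(m, a)
        assert (prof.fractions["EPB"] == 1.0).all()

    def test_generator_round_trip_recovers_probability(self):
        spec = CohortSpec(
            n_per_type={"EPB": 2000}, missing_rate=0.0, seed=17
        )
        m, truth, _ = generate_cohort(spec)
        prof = positivity_profiles(m, truth)
        assert prof.fractions.loc["CK19", "EPB"] == pytest.approx(0.90, abs=0.02)

    def test_unobserved_marker_reported_as_n_zero(self):
        m = make_matrix([[np.nan, 5], [np.nan, 20]])
        a = pd.Series(["ICC", "ICC"], index=m.scores.index)
        prof = positivity_profiles(m, a)
        assert np.isnan(prof.fractions.loc["m1", "ICC"])
        assert prof.counts.loc["m1", "ICC"] == 0

    def test_unclassified_samples_excluded(self):
        m = make_matrix(np.full((3, 2), 50.0))
        a = pd.Series(["EPB", "EPB", "unclassified"], index=m.scores.index)
        prof = positivity_profiles(m, a)
        assert list(prof.fractions.columns) == ["EPB"]
        assert prof.counts["EPB"].iloc[0] == 2
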