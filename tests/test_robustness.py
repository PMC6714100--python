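import numpy as np
import pytest

from conftest import random_ranking
from oracles import (
    oracle_continuity,
    oracle_identifiability,
    oracle_instability,
    oracle_k_sim,
    oracle_relaxed,
)
from rankrobust import (
    ConfidenceRegion,
    OverallRanking,
    Ranking,
    RankMatrix,
    k_similarity,
    overall_ranking,
    rank_continuity,
    rank_identifiability,
    rank_instability,
    relaxed_k_similarity,
    robustness_report,
    substream,
)


def ranking_from_dict(d):
    nodes = tuple(sorted(d))
    return Ranking(nodes=nodes, ranks=np.array([d[v] for v in nodes]))


def rank_matrix(rank_dicts, metric="m"):
    nodes = tuple(sorted(next(iter(rank_dicts.values()))))
    rm = RankMatrix(nodes=nodes)
    for theta, d in rank_dicts.items():
        rm.set(metric, theta, ranking_from_dict(d))
    return rm


def region(mu, nu):
    return ConfidenceRegion(mu=mu, nu=nu)


class TestKSimilarity:
    def test_identity_is_one(self, rng):
        a = random_ranking(tuple(f"n{i}" for i in range(20)), rng)
        for k in (0.05, 0.31, 1.0):
            assert k_similarity(a, a, k) == 1.0

    def test_constructed_two_thirds(self):
        # N=10, k=0.3: top-3 sets {x,y,z} vs {x,y,w} -> 2/3
        nodes = tuple("abcdefwxyz")
        a = {"x": 10, "y": 9, "z": 8, "w": 7, "a": 6, "b": 5, "c": 4, "d": 3, "e": 2, "f": 1}
        b = {"x": 10, "y": 9, "w": 8, "z": 7, "a": 6, "b": 5, "c": 4, "d": 3, "e": 2, "f": 1}
        sim = k_similarity(ranking_from_dict(a), ranking_from_dict(b), 0.3)
        assert sim == pytest.approx(2 / 3)

    def test_disjoint_top_sets_zero(self):
        n = 10
        d1 = {f"n{i}": i + 1 for i in range(n)}
        d2 = {f"n{i}": n - i for i in range(n)}
        sim = k_similarity(ranking_from_dict(d1), ranking_from_dict(d2), 0.2)
        assert sim == 0.0

    def test_symmetry_and_bounds(self, rng):
        nodes = tuple(f"n{i:02d}" for i in range(37))
        for _ in range(20):
            a, b = random_ranking(nodes, rng), random_ranking(nodes, rng)
            for k in (0.001, 0.03, 0.17, 0.5, 1.0):
                s1 = k_similarity(a, b, k)
                assert s1 == k_similarity(b, a, k)
                assert 0.0 <= s1 <= 1.0

    def test_mismatched_universes_rejected(self, rng):
        a = random_ranking(("a", "b"), rng)
        b = random_ranking(("a", "c"), rng)
        with pytest.raises(ValueError):
            k_similarity(a, b, 0.5)

    def test_k_out_of_range(self, rng):
        a = random_ranking(("a", "b"), rng)
        with pytest.raises(ValueError):
            k_similarity(a, a, 0.0)


class TestRelaxedKSimilarity:
    def test_alpha_one_reduces_to_k_similarity(self, rng):
        nodes = tuple(f"n{i:02d}" for i in range(25))
        for _ in range(50):
            a, b = random_ranking(nodes, rng), random_ranking(nodes, rng)
            for k in (0.04, 0.2, 0.52):
                assert relaxed_k_similarity(a, b, k, 1.0) == k_similarity(a, b, k)

    def test_constructed_one_half(self):
        # N=10, k=0.2, alpha=1.5: B top-2 {u,v}; A has u at rank 9
        # (inside A's top-3) and v at rank 5 (outside) -> 1/2
        rest = ["a", "b", "c", "d", "e", "f", "g", "h"]
        a = {"u": 9, "v": 5}
        for i, x in enumerate(rest):
            a[x] = [10, 8, 7, 6, 4, 3, 2, 1][i]
        b = {"u": 10, "v": 9}
        for i, x in enumerate(rest):
            b[x] = 8 - i
        sim = relaxed_k_similarity(
            ranking_from_dict(a), ranking_from_dict(b), 0.2, 1.5
        )
        assert sim == pytest.approx(0.5)

    def test_reference_equals_test_is_one(self, rng):
        a = random_ranking(tuple(f"n{i}" for i in range(30)), rng)
        for k, alpha in [(0.1, 1.5), (0.2, 2.0), (0.5, 2.0)]:
            assert relaxed_k_similarity(a, a, k, alpha) == 1.0

    def test_k_alpha_above_one_rejected(self, rng):
        a = random_ranking(tuple(f"n{i}" for i in range(10)), rng)
        with pytest.raises(ValueError):
            relaxed_k_similarity(a, a, 0.8, 1.5)

    def test_matches_oracle(self, rng):
        nodes = tuple(f"n{i:02d}" for i in range(41))
        for _ in range(30):
            a, b = random_ranking(nodes, rng), random_ranking(nodes, rng)
            ad, bd = a.as_dict(), b.as_dict()
            for k, alpha in [(0.05, 1.5), (0.1, 3.0), (0.25, 2.0)]:
                assert relaxed_k_similarity(a, b, k, alpha) == pytest.approx(
                    oracle_relaxed(ad, bd, k, alpha)
                )


class TestRankContinuity:
    def test_identical_rankings_give_one(self, rng):
        base = random_ranking(tuple(f"n{i:03d}" for i in range(50)), rng).as_dict()
        rm = rank_matrix({t: base for t in range(60, 66)})
        assert rank_continuity(rm, "m", region(60, 65)) == 1.0

    def test_disjoint_consecutive_tops_give_zero(self):
        # alternate between a ranking and its reversal: every top-5% set
        # at consecutive thresholds is disjoint for all k <= 0.05
        n = 200
        fwd = {f"n{i:03d}": i + 1 for i in range(n)}
        rev = {f"n{i:03d}": n - i for i in range(n)}
        rm = rank_matrix({60: fwd, 61: rev, 62: fwd, 63: rev})
        assert rank_continuity(rm, "m", region(60, 63)) == 0.0

    def test_matches_brute_force_on_toy_matrix(self, rng):
        nodes = tuple(f"n{i:03d}" for i in range(60))
        dicts = {
            t: random_ranking(nodes, rng).as_dict() for t in range(60, 64)
        }
        rm = rank_matrix(dicts)
        k_grid = [0.02, 0.05, 0.1, 0.25]
        got = rank_continuity(rm, "m", region(60, 63), k_grid=k_grid, cutoff=0.5)
        expected = oracle_continuity(dicts, k_grid, cutoff=0.5)
        assert got == pytest.approx(expected)

    def test_single_threshold_region_rejected(self, rng):
        base = random_ranking(("a", "b", "c"), rng).as_dict()
        rm = rank_matrix({60: base})
        with pytest.raises(ValueError):
            rank_continuity(rm, "m", region(60, 60))

    def test_extend_pair_policy_uses_boundary_pair(self, rng):
        nodes = tuple(f"n{i:03d}" for i in range(40))
        base = random_ranking(nodes, rng).as_dict()
        other = random_ranking(nodes, rng).as_dict()
        rm = rank_matrix({60: base, 61: base, 62: other})
        inside = rank_continuity(rm, "m", region(60, 61), k_grid=[0.1])
        extended = rank_continuity(
            rm, "m", region(60, 61), k_grid=[0.1], pair_policy="extend"
        )
        assert inside == 1.0
        assert extended < 1.0  # the (61, 62) boundary pair now counts


class TestRankIdentifiability:
    def overall_from(self, rm, reg, seed=0):
        return overall_ranking(rm, "m", reg, np.random.default_rng(seed))

    def test_perfect_agreement_is_one(self, rng):
        base = random_ranking(tuple(f"n{i:03d}" for i in range(40)), rng).as_dict()
        rm = rank_matrix({t: base for t in range(60, 64)})
        b = self.overall_from(rm, region(60, 63))
        assert rank_identifiability(rm, "m", b, top_n=10) == 1.0

    def test_controlled_overlap_gives_point_six(self):
        """One threshold's top-150 misses 40 of B's top-100 (N=1000)."""
        n = 1000
        nodes = tuple(f"n{i:04d}" for i in range(n))
        ident = {v: i + 1 for i, v in enumerate(nodes)}
        # shift B's top-60..99 nodes (ranks 901..940) below A's top-150 cut
        bad = dict(ident)
        # nodes ranked 901..940 in B get pushed to the bottom in this A
        moved = [v for v, r in ident.items() if 901 <= r <= 940]
        others = [v for v, r in ident.items() if not 901 <= r <= 940]
        a_theta = {}
        for i, v in enumerate(moved):
            a_theta[v] = i + 1
        for i, v in enumerate(sorted(others, key=ident.get)):
            a_theta[v] = len(moved) + i + 1
        rm = rank_matrix({60: ident, 61: a_theta})
        b = OverallRanking(
            metric="m", region=region(60, 61), ranking=ranking_from_dict(ident)
        )
        assert rank_identifiability(rm, "m", b, top_n=100) == pytest.approx(0.60)

    def test_min_over_wider_region_non_increasing(self, rng):
        nodes = tuple(f"n{i:03d}" for i in range(50))
        dicts = {t: random_ranking(nodes, rng).as_dict() for t in range(60, 70)}
        rm = rank_matrix(dicts)
        narrow_region, wide_region = region(62, 65), region(60, 69)
        rng0 = np.random.default_rng(0)
        b_narrow = overall_ranking(rm, "m", narrow_region, rng0)
        # same overall ranking B, min taken over more thresholds
        b_wide = OverallRanking(metric="m", region=wide_region,
                                ranking=b_narrow.ranking)
        narrow = rank_identifiability(rm, "m", b_narrow, top_n=5)
        wide = rank_identifiability(rm, "m", b_wide, top_n=5)
        assert wide <= narrow + 1e-12

    def test_top_n_too_large_rejected(self, rng):
        nodes = tuple(f"n{i}" for i in range(10))
        rm = rank_matrix({60: random_ranking(nodes, rng).as_dict(),
                          61: random_ranking(nodes, rng).as_dict()})
        b = self.overall_from(rm, region(60, 61))
        with pytest.raises(ValueError):
            rank_identifiability(rm, "m", b, top_n=9, alpha=1.5)

    def test_matches_oracle(self, rng):
        nodes = tuple(f"n{i:03d}" for i in range(80))
        dicts = {t: random_ranking(nodes, rng).as_dict() for t in range(60, 65)}
        rm = rank_matrix(dicts)
        b = self.overall_from(rm, region(60, 64))
        got = rank_identifiability(rm, "m", b, top_n=8, alpha=1.5)
        expected = oracle_identifiability(dicts, b.ranking.as_dict(), 8, 1.5)
        assert got == pytest.approx(expected)


class TestRankInstability:
    def test_constant_rankings_give_zero(self, rng):
        base = random_ranking(tuple(f"n{i:03d}" for i in range(30)), rng).as_dict()
        rm = rank_matrix({t: base for t in range(60, 64)})
        b = overall_ranking(rm, "m", region(60, 63), np.random.default_rng(0))
        assert rank_instability(rm, "m", b) == 0.0

    def test_full_swing_top_node(self):
        n = 100
        fwd = {f"n{i:03d}": i + 1 for i in range(n)}
        swapped = dict(fwd)
        top = "n099"
        bottom = "n000"
        swapped[top], swapped[bottom] = fwd[bottom], fwd[top]  # 100 <-> 1
        rm = rank_matrix({60: fwd, 61: swapped})
        b = OverallRanking(metric="m", region=region(60, 61),
                           ranking=ranking_from_dict(fwd))
        # |U| = 1, range(top) = 99 -> 0.99
        assert rank_instability(rm, "m", b) == pytest.approx(0.99)

    def test_matches_hand_computed_toy(self):
        n = 10
        d1 = {f"n{i}": i + 1 for i in range(n)}
        d2 = dict(d1)
        d2["n9"], d2["n7"] = d1["n7"], d1["n9"]  # top node 10 <-> 8
        rm = rank_matrix({60: d1, 61: d2})
        b = OverallRanking(metric="m", region=region(60, 61),
                           ranking=ranking_from_dict(d1))
        # U = {n9}; range = 10 - 8 = 2; 2/10 = 0.2
        assert rank_instability(rm, "m", b) == pytest.approx(0.2)

    def test_matches_oracle(self, rng):
        nodes = tuple(f"n{i:03d}" for i in range(120))
        dicts = {t: random_ranking(nodes, rng).as_dict() for t in range(60, 66)}
        rm = rank_matrix(dicts)
        b = overall_ranking(rm, "m", region(60, 65), np.random.default_rng(3))
        got = rank_instability(rm, "m", b)
        expected = oracle_instability(dicts, b.ranking.as_dict())
        assert got == pytest.approx(expected)


class TestRobustnessReport:
    def test_all_identical_rankings(self, rng):
        nodes = tuple(f"n{i:03d}" for i in range(40))
        base = random_ranking(nodes, rng).as_dict()
        rm = rank_matrix({t: base for t in range(60, 66)})
        rep = robustness_report(rm, region(60, 65), top_n=10)
        row = rep.table.iloc[0]
        assert row["continuity"] == 1.0
        assert row["identifiability"] == 1.0
        assert row["instability"] == 0.0

    def test_single_ranking_region_is_error(self, rng):
        nodes = tuple(f"n{i}" for i in range(10))
        rm = rank_matrix({60: random_ranking(nodes, rng).as_dict()})
        with pytest.raises(ValueError):
            robustness_report(rm, region(60, 60), top_n=3)

    def test_top_n_capped_with_warning(self, rng):
        nodes = tuple(f"n{i:02d}" for i in range(30))
        rm = rank_matrix({60: random_ranking(nodes, rng).as_dict(),
                          61: random_ranking(nodes, rng).as_dict()})
        with pytest.warns(UserWarning, match="top_n reduced"):
            rep = robustness_report(rm, region(60, 61), top_n=100)
        assert rep.params["top_n"] == 20  # floor(30 / 1.5)

    def test_equals_componentwise_recomputation(self, rng):
        nodes = tuple(f"n{i:03d}" for i in range(60))
        dicts = {t: random_ranking(nodes, rng).as_dict() for t in range(60, 65)}
        rm = rank_matrix(dicts)
        reg = region(60, 64)
        rep = robustness_report(rm, reg, top_n=10, master_seed=9)
        b = overall_ranking(rm, "m", reg, substream(9, "overall", "m"))
        row = rep.table.iloc[0]
        assert row["continuity"] == rank_continuity(rm, "m", reg)
        assert row["identifiability"] == rank_identifiability(rm, "m", b, top_n=10)
        assert row["instability"] == rank_instability(rm, "m", b)

    def test_measures_within_bounds_on_random_matrices(self, rng):
        nodes = tuple(f"n{i:03d}" for i in range(50))
        for _ in range(5):
            dicts = {t: random_ranking(nodes, rng).as_dict()
                     for t in range(60, 64)}
            rep = robustness_report(rank_matrix(dicts), region(60, 63), top_n=10)
            row = rep.table.iloc[0]
            for col in ("continuity", "identifiability", "instability"):
                assert 0.0 <= row[col] <= 1.0


def test_oracle_k_sim_cross_check(rng):
    """The package and the set-arithmetic oracle agree on a grid."""
    nodes = tuple(f"n{i:03d}" for i in range(73))
    for _ in range(20):
        a, b = random_ranking(nodes, rng), random_ranking(nodes, rng)
        for k in (0.001, 0.013, 0.05, 0.33, 1.0):
            assert k_similarity(a, b, k) == pytest.approx(
                oracle_k_sim(a.as_dict(), b.as_dict(), k)
            )
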