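"""Running-sum enrichment score and permutation significance."""

from itertools import combinations

import numpy as np
import pytest

from pxea.proximity import ProximityResult
from pxea.pxea import (
    RankedPathways,
    common_span,
    permutation_p,
    pxea_screen,
    rank_pathways_for_drug,
    running_sum_es,
)
from pxea.proximity import PathwaySpan
from pxea.synthetic_data import plant_disease_module


def ranking(n: int) -> RankedPathways:
    return RankedPathways(tuple((f"p{i}", float(i)) for i in range(n)))


def brute_force_es(hit_flags: list[bool]) -> float:
    """Prefix-sum oracle: walk the ranking accumulating the increments."""
    n, k = len(hit_flags), sum(hit_flags)
    best = total = 0.0
    for is_hit in hit_flags:
        total += (n - k) / k if is_hit else -k / (n - k)
        best = max(best, total)
    return best


class TestRunningSumEs:
    def test_all_hits_on_top_reach_maximum(self):
        D = ranking(10)
        assert running_sum_es(D, {"p0", "p1", "p2"}) == pytest.approx(7.0)

    def test_hits_at_bottom_floor_at_zero(self):
        D = ranking(4)
        assert running_sum_es(D, {"p2", "p3"}) == pytest.approx(0.0)

    def test_top_placement_is_maximal(self):
        D = ranking(8)
        top = running_sum_es(D, {"p0", "p1"})
        for pair in combinations(D.ids, 2):
            assert running_sum_es(D, set(pair)) <= top + 1e-12

    def test_full_sum_identity(self):
        # the increments sum to |D| - 2|C| over the whole ranking
        n, k = 9, 4
        hit, miss = (n - k) / k, -k / (n - k)
        assert k * hit + (n - k) * miss == pytest.approx(n - 2 * k)

    def test_degenerate_c_rejected(self):
        D = ranking(5)
        with pytest.raises(ValueError):
            running_sum_es(D, set())
        with pytest.raises(ValueError):
            running_sum_es(D, set(D.ids))
        with pytest.raises(ValueError, match="absent"):
            running_sum_es(D, {"p0", "ghost"})

    def test_matches_brute_force_for_all_small_placements(self):
        # exhaustive: every |D| <= 8, every |C|, every placement of C
        for n in range(2, 9):
            D = ranking(n)
            for k in range(1, n):
                for placement in combinations(range(n), k):
                    C = {f"p{i}" for i in placement}
                    flags = [i in placement for i in range(n)]
                    assert running_sum_es(D, C) == pytest.approx(
                        brute_force_es(flags)
                    ), (n, k, placement)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(2, 30))
            k = int(rng.integers(1, n))
            C = {f"p{i}" for i in rng.choice(n, size=k, replace=False)}
            es = running_sum_es(ranking(n), C)
            assert 0 <= es <= n - k + 1e-12


class TestPermutationP:
    def test_top_placement_p_zero_reported_as_bound(self):
        D = ranking(10)
        C = {"p0", "p1", "p2"}
        p, _ = permutation_p(D, C, n_perm=500, seed=0)
        assert p == 0.0

    def test_matches_exhaustive_enumeration(self):
        # |D|=6, |C|=2: exact null over the C(6,2)=15 equally likely
        # placements; sampled p within 3 Monte-Carlo standard errors
        n, k = 6, 2
        D = ranking(n)
        exact_null = [
            brute_force_es([i in placement for i in range(n)])
            for placement in combinations(range(n), k)
        ]
        for C in ({"p1", "p3"}, {"p0", "p5"}, {"p4", "p5"}):
            es_obs = running_sum_es(D, C)
            p_exact = sum(e > es_obs + 1e-12 for e in exact_null) / len(exact_null)
            p_mc, null = permutation_p(D, C, n_perm=10_000, seed=3)
            se = np.sqrt(max(p_exact * (1 - p_exact), 1e-12) / 10_000)
            assert abs(p_mc - p_exact) <= max(3 * se, 1e-9), (C, p_mc, p_exact)
            assert len(null) == 10_000

    def test_null_mean_matches_enumeration(self):
        n, k = 7, 3
        D = ranking(n)
        exact = [
            brute_force_es([i in pl for i in range(n)])
            for pl in combinations(range(n), k)
        ]
        _, null = permutation_p(D, {"p0", "p1", "p2"}, n_perm=10_000, seed=5)
        se = np.std(exact) / np.sqrt(10_000)
        assert abs(null.mean() - np.mean(exact)) <= 4 * se

    def test_distribution_free(self):
        # p depends on D only through the positions of C
        D1 = RankedPathways(tuple((f"p{i}", -5.0 + i * 0.1) for i in range(8)))
        D2 = RankedPathways(tuple((f"p{i}", float(i * i)) for i in range(8)))
        C = {"p2", "p5"}
        p1, _ = permutation_p(D1, C, n_perm=2000, seed=7)
        p2, _ = permutation_p(D2, C, n_perm=2000, seed=7)
        assert p1 == p2

    def test_smallest_reportable_nonzero_p(self):
        assert 1 / 10_000 == pytest.approx(1e-4)

    def test_zero_p_reported_as_resolution_bound(self):
        from pxea.pxea import PxeaResult

        res = PxeaResult(es=5.0, p=0.0, p_adj=0.0, n_perm=10_000, seed=0)
        assert res.p_text() == "< 0.0001"
        res = PxeaResult(es=5.0, p=0.02, p_adj=0.05, n_perm=10_000, seed=0)
        assert res.p_text() == "0.02"


def _res(z: float, d_obs: float = 1.0) -> ProximityResult:
    return ProximityResult(d_obs=d_obs, mu=0.0, sigma=1.0, z=z,
                           n_random=10, seed=0)


class TestRankedPathways:
    def test_sorted_by_z_then_d_then_id(self):
        D = RankedPathways.from_results([
            ("b", _res(-1.0, d_obs=2.0)),
            ("a", _res(-1.0, d_obs=2.0)),
            ("c", _res(-3.0)),
            ("d", _res(-1.0, d_obs=0.5)),
        ])
        assert D.ids == ("c", "d", "a", "b")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RankedPathways((("a", 0.0), ("a", 1.0)))


class TestCommonSpan:
    def _span(self, ids):
        entries = tuple((pid, _res(-3.0)) for pid in ids)
        return PathwaySpan("d", entries)

    def test_identity_and_disjoint(self):
        a = self._span(["p1", "p2"])
        assert common_span(a, a) == {"p1", "p2"}
        assert common_span(a, self._span(["p9"])) == set()

    def test_sizes_like_span_overlap(self):
        a = self._span([f"p{i}" for i in range(170)])
        b = self._span([f"p{i}" for i in range(135, 217)])
        assert len(a.pathway_ids) == 170 and len(b.pathway_ids) == 82
        assert len(common_span(a, b)) == 35


class TestRankAndScreen:
    def test_self_pathway_ranks_first(self, small_ba_graph):
        g = small_ba_graph
        module = plant_disease_module(g, 6, seed=1)
        others = sorted(set(g.nodes) - module)
        pathways = [
            ("self", module),
            ("far1", set(others[:6])),
            ("far2", set(others[100:106])),
        ]
        D = rank_pathways_for_drug(g, module, pathways, n_random=100,
                                   min_bin_size=50, seed=2)
        assert D.ids[0] == "self"

    def test_ranking_deterministic(self, small_ba_graph):
        g = small_ba_graph
        nodes = sorted(g.nodes)
        pathways = [(f"pw{i}", set(nodes[i * 10:(i + 1) * 10])) for i in range(5)]
        a = rank_pathways_for_drug(g, nodes[:4], pathways, n_random=50,
                                   min_bin_size=50, seed=5)
        b = rank_pathways_for_drug(g, nodes[:4], pathways, n_random=50,
                                   min_bin_size=50, seed=5)
        assert a.entries == b.entries

    def test_no_targets_rejected(self, small_ba_graph):
        with pytest.raises(ValueError, match="no targets"):
            rank_pathways_for_drug(small_ba_graph, {"alien"}, [("p", {"G0001"})])

    def test_identical_target_drugs_score_identically(self, small_ba_graph):
        g = small_ba_graph
        nodes = sorted(g.nodes)
        pathways = [(f"pw{i}", set(nodes[i * 12:(i + 1) * 12])) for i in range(4)]
        table = {"drugA": set(nodes[:3]), "drugB": set(nodes[:3]),
                 "drugC": set(nodes[40:43])}
        df = pxea_screen(g, table, pathways, {"pw0"}, n_random=50,
                         n_perm=200, min_bin_size=50, seed=0)
        rows = df.set_index("drug_id")
        assert rows.loc["drugA", "es"] == rows.loc["drugB", "es"]
        assert rows.loc["drugA", "p"] == rows.loc["drugB", "p"]

    def test_empty_drug_table(self, small_ba_graph):
        df = pxea_screen(small_ba_graph, {}, [("p", {"G0001"}), ("q", {"G0002"})],
                         {"p"}, n_random=10, n_perm=10, seed=0)
        assert len(df) == 0

    def test_unusable_drug_reported_not_scored(self, small_ba_graph):
        g = small_ba_graph
        nodes = sorted(g.nodes)
        pathways = [("pw0", set(nodes[:10])), ("pw1", set(nodes[10:20]))]
        df = pxea_screen(g, {"ok": set(nodes[:2]), "ghost": {"alien"}},
                         pathways, {"pw0"}, n_random=20, n_perm=50,
                         min_bin_size=50, seed=1)
        ghost = df[df.drug_id == "ghost"].iloc[0]
        assert np.isnan(ghost.es) and ghost.n_targets_used == 0
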