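"""Tests for near-neighbor-network growth, joining and automatic thresholds.

The brute-force oracle used here enumerates, for a seed protein, every
subset of the seed's threshold-neighbors whose set-wise completeness meets
the completeness threshold and keeps only the maximal ones — the ground
truth the greedy growth is compared against.
"""

import itertools

import numpy as np
import pytest

from hc4n.data_io import extract_subset
from hc4n.fourn import Cluster, auto_thresholds, grow_network, join_clusters, run_4n
from hc4n.similarity import (
    SimilarityThresholds,
    co_occurrence_matrix,
    min_co_occurrence,
    set_completeness,
)

from conftest import occurrence_matrix, random_occurrence_matrix


def maximal_feasible_sets(co, seed, th):
    """All maximal sets S containing seed with every member a t_co-neighbor
    of seed and completeness(S) >= t_comp (occurrence data)."""
    si = co.index(seed)
    neighbors = [
        p for p in co.protein_ids
        if p != seed and co.value(seed, p) >= th.t_co - 1e-9
    ]
    feasible = []
    for r in range(1, len(neighbors) + 1):
        for combo in itertools.combinations(neighbors, r):
            s = frozenset({seed, *combo})
            if set_completeness(co, s, th.t_co) >= th.t_comp - 1e-9:
                feasible.append(s)
    return [s for s in feasible if not any(s < t for t in feasible)]


class TestGrowNetwork:
    def test_only_candidate_joins(self):
        m = occurrence_matrix({"a": "11", "b": "11"})
        co = co_occurrence_matrix(m)
        cl = grow_network(co, m, "a", SimilarityThresholds(0.5, 0.5, 40))
        assert cl.members == {"a", "b"}
        assert cl.min_co == 1.0

    def test_isolated_seed_gives_none(self):
        m = occurrence_matrix({"a": "110", "b": "001", "c": "001"})
        co = co_occurrence_matrix(m)
        assert grow_network(co, m, "a", SimilarityThresholds(0.5, 1.0, 40)) is None

    def test_triangle_excludes_weak_fourth(self):
        # a,b,c pairwise co-occur strongly; d barely overlaps anyone
        m = occurrence_matrix(
            {"a": "111100", "b": "111010", "c": "111001", "d": "000111"}
        )
        co = co_occurrence_matrix(m)
        assert co.value("a", "b") == pytest.approx(0.6)
        assert co.value("a", "d") == pytest.approx(1 / 6)
        cl = grow_network(co, m, "a", SimilarityThresholds(0.5, 1.0, 40))
        assert cl.members == {"a", "b", "c"}

    def test_unknown_seed_is_error(self, small_matrix):
        co = co_occurrence_matrix(small_matrix)
        with pytest.raises(KeyError):
            grow_network(co, small_matrix, "zz", SimilarityThresholds(0.5, 1.0, 40))

    def test_result_is_a_maximal_feasible_set_most_of_the_time(self):
        """Greedy growth lands on a brute-force-maximal set in >= 95% of
        random instances (the remainder are greedy-vs-optimal cases)."""
        rng = np.random.default_rng(2024)
        agree = total = 0
        for _ in range(200):
            m = random_occurrence_matrix(rng)
            co = co_occurrence_matrix(m)
            t_co = float(rng.choice([0.2, 0.3, 0.4, 0.5]))
            t_comp = float(rng.choice([0.6, 0.8, 1.0]))
            th = SimilarityThresholds(t_co, t_comp, 40)
            seed = str(rng.choice(m.protein_ids))
            got = grow_network(co, m, seed, th)
            oracle = maximal_feasible_sets(co, seed, th)
            total += 1
            if got is None:
                agree += not oracle
            else:
                # grown set is always feasible…
                assert set_completeness(co, got.members, t_co) >= t_comp - 1e-9
                # …and usually maximal
                agree += got.members in oracle
        assert agree / total >= 0.95


class TestJoinClusters:
    def c(self, *names):
        return Cluster(frozenset(names), 0.5)

    def test_majority_overlap_merges(self):
        out = join_clusters([self.c("a", "b", "c"), self.c("b", "c", "d")], 0.5)
        assert [cl.members for cl in out] == [frozenset("abcd")]

    def test_disjoint_clusters_untouched(self):
        out = join_clusters([self.c("a", "b"), self.c("c", "d")], 0.5)
        assert len(out) == 2

    def test_overlap_below_threshold_untouched(self):
        out = join_clusters([self.c("a", "b", "c"), self.c("b", "c", "d")], 0.7)
        assert len(out) == 2  # 2/3 < 0.7

    def test_identical_sets_deduplicated_even_at_threshold_one(self):
        out = join_clusters([self.c("a", "b"), self.c("a", "b"), self.c("b", "c")], 1.0)
        assert len(out) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        proteins = [f"p{i}" for i in range(8)]
        clusters = [
            Cluster(frozenset(rng.choice(proteins, size=rng.integers(2, 5), replace=False)), 0.3)
            for _ in range(6)
        ]
        once = join_clusters(clusters, 0.5)
        twice = join_clusters(once, 0.5)
        assert [c.members for c in once] == [c.members for c in twice]

    def test_min_co_recomputed_from_matrix(self, two_cliques):
        co = co_occurrence_matrix(two_cliques)
        out = join_clusters(
            [Cluster(frozenset({"a1", "a2"}), 1.0), Cluster(frozenset({"a1", "a2", "a3"}), 1.0)],
            0.5,
            co=co,
        )
        assert out[0].min_co == pytest.approx(min_co_occurrence(co, out[0].members))


class TestRun4N:
    def test_two_cliques_found_exactly(self, two_cliques):
        res = run_4n(two_cliques, SimilarityThresholds(0.5, 1.0, 40))
        assert sorted(sorted(c.members) for c in res.clusters) == [
            ["a1", "a2", "a3"],
            ["b1", "b2", "b3"],
        ]
        assert res.lost_proteins == frozenset()

    def test_strict_co_occurrence_loses_unmatched_protein(self):
        m = occurrence_matrix({"a": "110", "b": "110", "c": "011"})
        res = run_4n(m, SimilarityThresholds(1.0, 1.0, 40))
        assert res.lost_proteins == {"c"}

    def test_join_overlap_one_keeps_deduplicated_networks(self, two_cliques):
        res = run_4n(two_cliques, SimilarityThresholds(0.5, 1.0, 40), join_overlap=1.0)
        assert len(res.clusters) == len(res.raw_networks)

    def test_every_cluster_meets_completeness(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            m = random_occurrence_matrix(rng)
            co = co_occurrence_matrix(m)
            th = SimilarityThresholds(0.3, 0.8, 40)
            res = run_4n(m, th)
            for cl in res.raw_networks:
                assert set_completeness(co, cl.members, th.t_co) >= th.t_comp - 1e-9

    def test_deterministic_and_order_invariant(self):
        rng = np.random.default_rng(42)
        m = random_occurrence_matrix(rng)
        th = SimilarityThresholds(0.3, 1.0, 40)
        sets1 = {c.members for c in run_4n(m, th).clusters}
        assert {c.members for c in run_4n(m, th).clusters} == sets1
        # permute rows and columns
        perm_r = rng.permutation(m.n_proteins)
        perm_c = rng.permutation(m.n_ips)
        from hc4n.data_io import IPMSMatrix

        m2 = IPMSMatrix(
            [m.protein_ids[i] for i in perm_r],
            [m.ip_ids[j] for j in perm_c],
            m.values[np.ix_(perm_r, perm_c)],
            m.data_kind,
        )
        assert {c.members for c in run_4n(m2, th).clusters} == sets1

    def test_raising_t_co_never_grows_a_seed_network(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            m = random_occurrence_matrix(rng)
            co = co_occurrence_matrix(m)
            seed = str(rng.choice(m.protein_ids))
            lo = grow_network(co, m, seed, SimilarityThresholds(0.25, 1.0, 40))
            hi = grow_network(co, m, seed, SimilarityThresholds(0.5, 1.0, 40))
            n_lo = 1 if lo is None else len(lo.members)
            n_hi = 1 if hi is None else len(hi.members)
            assert n_hi <= n_lo


class TestAutoThresholds:
    def test_two_cliques_support_maximum_strictness(self, two_cliques):
        th = auto_thresholds(two_cliques)
        assert th.t_co == 1.0 and th.t_comp == 1.0

    def test_t_co_capped_by_weakest_best_partner(self):
        # c's best partner is a at 0.35 > threshold steps below
        m = occurrence_matrix(
            {
                "a": "1" * 17 + "000",
                "b": "1" * 17 + "000",
                "c": "1" * 7 + "0" * 10 + "111",
            }
        )
        co = co_occurrence_matrix(m)
        assert co.value("a", "c") == pytest.approx(0.35)
        th = auto_thresholds(m)
        assert th.t_co <= 0.35

    def test_fixed_t_co_with_feasible_completeness_returns_one(self, two_cliques):
        th = auto_thresholds(two_cliques, SimilarityThresholds(t_co=0.5))
        assert th.t_comp == 1.0

    def test_returned_setting_loses_nothing_and_next_notch_loses(self):
        rng = np.random.default_rng(31)
        m = random_occurrence_matrix(rng)
        th = auto_thresholds(m)
        assert not run_4n(m, th).lost_proteins
        stricter = SimilarityThresholds(round(th.t_co + 0.01, 10), th.t_comp, th.t_ab)
        if stricter.t_co <= 1.0:
            assert run_4n(m, stricter).lost_proteins

    def test_infeasible_reports_never_clusterable_proteins(self):
        # 'c' shares no IP with anyone: never clusterable at any threshold
        m = occurrence_matrix({"a": "110", "b": "110", "c": "001"})
        with pytest.raises(ValueError, match="c"):
            auto_thresholds(m, grid_step=0.5)
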