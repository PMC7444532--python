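"""Apriori clique miner: join rule, support counting, oracle equivalence."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braincliques.mining import (
    MiningConfig,
    apriori_join,
    as_threshold,
    brute_force_mine,
    contains_pattern,
    count_support,
    downward_closure,
    maximal_patterns,
    mine_frequent_cliques,
)

from conftest import make_db, random_db


def as_set(records):
    return {(r.pattern, r.count) for r in records}


class TestContainsPattern:
    def test_triangle_contained(self):
        db = make_db([[(1, 2), (1, 3), (2, 3)]])
        assert contains_pattern(db.graphs[0], (1, 2, 3))

    def test_path_missing_closing_edge(self):
        db = make_db([[(1, 2), (2, 3)]])
        assert not contains_pattern(db.graphs[0], (1, 2, 3))

    def test_pair_pattern_equals_edge_membership(self):
        db = make_db([[(0, 1), (2, 3)]])
        g = db.graphs[0]
        for i, j in itertools.combinations(range(4), 2):
            assert contains_pattern(g, (i, j)) == ((i, j) in g.edges)

    def test_out_of_atlas_vertex_rejected(self):
        db = make_db([[(0, 1)]], n_vertices=2)
        with pytest.raises(ValueError, match="atlas"):
            contains_pattern(db.graphs[0], (0, 7))

    def test_non_canonical_pattern_rejected(self):
        db = make_db([[(0, 1)]])
        with pytest.raises(ValueError, match="ascending"):
            contains_pattern(db.graphs[0], (1, 0))


class TestCountSupport:
    def test_identical_triangles(self, triangle_db):
        assert count_support(triangle_db, (0, 1, 2)) == 5

    def test_empty_database(self):
        db = make_db([[(0, 1)]])
        db.graphs = []
        db.group_of = {}
        assert count_support(db, (0, 1)) == 0

    def test_matches_per_graph_edge_rescan(self, rng):
        db = random_db(rng, n_vertices=6, n_graphs=10, p=0.5)
        for pattern in [(0, 1), (1, 3, 5), (0, 2, 4), (0, 1, 2, 3)]:
            expected = sum(
                all(tuple(sorted(e)) in g.edges
                    for e in itertools.combinations(pattern, 2))
                for g in db.graphs
            )
            assert count_support(db, pattern) == expected


class TestAprioriJoin:
    def test_shared_prefix_joins(self):
        assert apriori_join((1, 2, 3), (1, 2, 5)) == (1, 2, 3, 5)

    def test_differing_prefix_rejected(self):
        assert apriori_join((1, 2, 3), (1, 4, 5)) is None

    def test_reversed_order_consumed_once(self):
        # the pair is consumed only in sorted order of last vertices
        assert apriori_join((1, 2, 5), (1, 2, 3)) is None

    def test_non_canonical_input_rejected(self):
        with pytest.raises(ValueError):
            apriori_join((3, 2, 1), (1, 2, 5))

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apriori_join((1, 2), (1, 2, 3))


class TestThreshold:
    def test_float_goes_through_decimal_string(self):
        assert as_threshold(0.8) == Fraction(4, 5)

    def test_inclusive_at_exact_boundary(self):
        # edge in 4 of 5 graphs: 4/5 >= 80% must be reported
        db = make_db([[(0, 1)]] * 4 + [[]], n_vertices=2)
        recs = mine_frequent_cliques(db, MiningConfig(threshold=0.8))
        assert as_set(recs) == {((0, 1), 4)}

    def test_just_below_boundary_excluded(self):
        db = make_db([[(0, 1)]] * 3 + [[], []], n_vertices=2)
        recs = mine_frequent_cliques(db, MiningConfig(threshold=0.8))
        assert recs == []

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            MiningConfig(threshold=0.0)
        with pytest.raises(ValueError):
            MiningConfig(threshold=1.5)


class TestMineFrequentCliques:
    def test_all_subsets_of_k4(self):
        k4 = list(itertools.combinations(range(1, 5), 2))
        db = make_db([k4] * 5, n_vertices=5)
        recs = mine_frequent_cliques(db, MiningConfig(threshold=0.8))
        assert len(recs) == 11  # 6 edges + 4 triangles + 1 four-clique
        assert all(r.count == 5 for r in recs)
        sizes = sorted(r.size for r in recs)
        assert sizes == [2] * 6 + [3] * 4 + [4]

    def test_empty_database_rejected(self):
        db = make_db([[(0, 1)]])
        db.graphs = []
        db.group_of = {}
        with pytest.raises(ValueError, match="empty"):
            mine_frequent_cliques(db)

    def test_max_size_caps_levels(self, triangle_db):
        recs = mine_frequent_cliques(
            triangle_db, MiningConfig(threshold=1.0, max_size=2)
        )
        assert {r.size for r in recs} == {2}

    def test_graph_order_invariance(self, rng):
        db = random_db(rng, n_vertices=10, n_graphs=15, p=0.5)
        perm = rng.permutation(len(db.graphs))
        db_shuffled = make_db(
            [sorted(db.graphs[i].edges) for i in perm], n_vertices=10
        )
        a = as_set(mine_frequent_cliques(db, MiningConfig(0.6)))
        b = as_set(mine_frequent_cliques(db_shuffled, MiningConfig(0.6)))
        assert a == b

    def test_threshold_monotonicity(self, rng):
        db = random_db(rng, n_vertices=10, n_graphs=20, p=0.6)
        low = {r.pattern for r in mine_frequent_cliques(db, MiningConfig(0.5))}
        high = {r.pattern for r in mine_frequent_cliques(db, MiningConfig(0.75))}
        assert high <= low


def assert_anti_monotone(records):
    """Downward closure with monotone counts, as every mined family must be."""
    by_pattern = {r.pattern: r.count for r in records}
    for r in records:
        if r.size < 3:
            continue
        for sub in itertools.combinations(r.pattern, r.size - 1):
            assert sub in by_pattern, f"missing sub-pattern {sub} of {r.pattern}"
            assert by_pattern[sub] >= r.count


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_vertices,n_graphs,p,threshold", [
        (6, 5, 0.8, 0.6),
        (10, 20, 0.5, 0.6),
        (12, 20, 0.6, 0.6),
        (14, 50, 0.3, 0.5),
        (8, 30, 0.9, 0.9),
    ])
    def test_matches_brute_force(self, rng, n_vertices, n_graphs, p, threshold):
        db = random_db(rng, n_vertices, n_graphs, p)
        cfg = MiningConfig(threshold=threshold)
        assert as_set(mine_frequent_cliques(db, cfg)) == as_set(
            brute_force_mine(db, cfg)
        )

    def test_anti_monotonicity_of_mined_families(self, rng):
        for _ in range(10):
            db = random_db(rng, 10, 15, rng.uniform(0.3, 0.8))
            assert_anti_monotone(mine_frequent_cliques(db, MiningConfig(0.6)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**32 - 1),
        n_vertices=st.integers(4, 12),
        n_graphs=st.integers(1, 25),
        p=st.floats(0.1, 0.9),
        threshold=st.sampled_from([0.5, 0.6, 0.8, 1.0]),
    )
    def test_property_oracle_equivalence(self, seed, n_vertices, n_graphs, p,
                                         threshold):
        db = random_db(np.random.default_rng(seed), n_vertices, n_graphs, p)
        cfg = MiningConfig(threshold=threshold)
        mined = mine_frequent_cliques(db, cfg)
        assert as_set(mined) == as_set(brute_force_mine(db, cfg))
        assert_anti_monotone(mined)


class TestBruteForce:
    def test_single_triangle_full_threshold(self):
        db = make_db([[(0, 1), (0, 2), (1, 2)]], n_vertices=3)
        recs = brute_force_mine(db, MiningConfig(threshold=1.0))
        assert {r.pattern for r in recs} == {(0, 1), (0, 2), (1, 2), (0, 1, 2)}

    def test_edgeless_graphs_yield_nothing(self):
        db = make_db([[], []], n_vertices=4)
        assert brute_force_mine(db, MiningConfig(0.5)) == []

    def test_refuses_large_atlas(self):
        db = make_db([[(0, 1)]], n_vertices=25)
        with pytest.raises(ValueError, match="20 vertices"):
            brute_force_mine(db)


class TestMaximalPatterns:
    def test_triangle_dominates_its_edges(self, triangle_db):
        recs = mine_frequent_cliques(triangle_db, MiningConfig(1.0))
        assert {r.pattern for r in maximal_patterns(recs)} == {(0, 1, 2)}

    def test_incomparable_patterns_both_kept(self):
        db = make_db([[(1, 2), (3, 4)]] * 3, n_vertices=5)
        recs = mine_frequent_cliques(db, MiningConfig(1.0))
        assert {r.pattern for r in maximal_patterns(recs)} == {(1, 2), (3, 4)}

    def test_matches_quadratic_subset_filter(self, rng):
        db = random_db(rng, 10, 20, 0.6)
        recs = mine_frequent_cliques(db, MiningConfig(0.6))
        got = {r.pattern for r in maximal_patterns(recs)}
        sets = [frozenset(r.pattern) for r in recs]
        expected = {
            r.pattern
            for r in recs
            if not any(frozenset(r.pattern) < s for s in sets)
        }
        assert got == expected


class TestDownwardClosure:
    def test_closure_of_four_clique(self):
        closed = downward_closure([(1, 2, 3, 4)])
        assert len(closed) == 11
        assert (1, 3) in closed and (1, 2, 4) in closed
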