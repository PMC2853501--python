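import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statelump.model import ReactionSpec, build_from_reactions
from statelump.simulate import default_time_grid, simulate
from statelump.timescale import (
    DGFR,
    build_lumping_scheme,
    classify_sink_clusters,
    connectivity_matrix,
    eliminate_negligible,
    find_dgfrs,
    negligible_states,
    slow_states,
    split_fast_slow,
    strong_components,
    suggest_epsilon,
)

# the five-node illustration graphs: a: S1->S2, b: S2->S3, c: S3->S4,
# d: S3->S5, e: S5->S2, and (G2 only) f: S4->S3
G1_EDGES = {"a": (0, 1), "b": (1, 2), "c": (2, 3), "d": (2, 4), "e": (4, 1)}
G2_EDGES = dict(G1_EDGES, f=(3, 2))


def _graph_model(edges, fast_names, fast=1e4, slow=1.0):
    rs = [
        ReactionSpec(s, t, name, fast if name in fast_names else slow)
        for name, (s, t) in edges.items()
    ]
    return build_from_reactions(rs, 5)


class TestSplitFastSlow:
    def test_six_state_split(self, m6):
        split = split_fast_slow(m6, 100.0)
        assert split.fast_parameters == {"k32", "k23", "k43", "k34", "k54", "k45", "k65", "k56"}
        assert split.slow_parameters == {"k12", "k13"}
        assert np.allclose(split.A_f + split.A_s, m6.A)

    def test_epsilon_above_all_rates(self, m6):
        split = split_fast_slow(m6, 1e6)
        assert np.all(split.A_f == 0)
        assert np.allclose(split.A_s, m6.A)

    def test_epsilon_below_all_rates(self, m6):
        split = split_fast_slow(m6, 1e-3)
        assert np.all(split.A_s == 0)
        assert np.allclose(split.A_f, m6.A)

    def test_dimension_bookkeeping(self, m26):
        split = split_fast_slow(m26, 1000.0)
        assert len(split.fast_parameters) + len(split.slow_parameters) == len(m26.reactions)

    def test_epsilon_must_be_positive(self, m6):
        with pytest.raises(ValueError):
            split_fast_slow(m6, 0.0)


class TestConnectivityMatrix:
    def test_graph_g1_fast_block(self):
        m = _graph_model(G1_EDGES, fast_names={"b", "d", "e"})
        split = split_fast_slow(m, 100.0)
        Mc = connectivity_matrix(split.A_f)
        block = {1, 2, 4}
        for i, j in itertools.combinations(range(5), 2):
            expect = i in block and j in block
            assert bool(Mc[i, j]) == expect

    def test_zero_matrix(self):
        Mc = connectivity_matrix(np.zeros((4, 4)))
        assert not Mc[~np.eye(4, dtype=bool)].any()

    def test_chain_all_connected(self):
        # independent oracle: brute-force transitive closure of 1->2->3
        rs = [ReactionSpec(0, 1, "a", 10.0), ReactionSpec(1, 2, "b", 10.0)]
        m = build_from_reactions(rs, 3)
        split = split_fast_slow(m, 1.0)
        Mc = connectivity_matrix(split.A_f)
        sym = {(0, 1), (1, 0), (1, 2), (2, 1)}
        oracle = np.zeros((3, 3), dtype=bool)
        reach = dict(sym)
        for i, j in itertools.product(range(3), repeat=2):
            # BFS on symmetrised edges
            seen, stack = {i}, [i]
            while stack:
                u = stack.pop()
                for a, b in sym:
                    if a == u and b not in seen:
                        seen.add(b)
                        stack.append(b)
            oracle[i, j] = j in seen and i != j or (i == j and len(seen) > 1)
        assert np.array_equal(Mc & ~np.eye(3, dtype=bool), oracle & ~np.eye(3, dtype=bool))
        assert Mc[0, 2] and Mc[2, 0]

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_matrix_powers_agree_with_bfs(self, data):
        n = data.draw(st.integers(2, 7))
        edges = data.draw(
            st.lists(
                st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(
                    lambda e: e[0] != e[1]
                ),
                max_size=10,
                unique=True,
            )
        )
        A = np.zeros((n, n))
        for s, t in edges:
            A[t, s] = 1.0
        Mc = connectivity_matrix(A)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)
        for i, j in itertools.combinations(range(n), 2):
            same = any(i in c and j in c for c in nx.connected_components(g))
            assert bool(Mc[i, j]) == same


class TestFindDgfrs:
    def test_six_state_single_dgfr(self, m6):
        dgfrs = find_dgfrs(split_fast_slow(m6, 100.0))
        assert len(dgfrs) == 1
        assert dgfrs[0].member_states == frozenset({1, 2, 3, 4, 5})

    def test_26_state_five_groups(self, m26):
        dgfrs = find_dgfrs(split_fast_slow(m26, 1000.0))
        assert len(dgfrs) == 5
        members = [d.member_states for d in dgfrs]
        assert all(a.isdisjoint(b) for a, b in itertools.combinations(members, 2))

    def test_no_fast_reactions(self, m6):
        assert find_dgfrs(split_fast_slow(m6, 1e6)) == []

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_dgfrs_match_bfs_components(self, data):
        n = data.draw(st.integers(3, 7))
        edges = data.draw(
            st.lists(
                st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(
                    lambda e: e[0] != e[1]
                ),
                min_size=1,
                max_size=10,
                unique=True,
            )
        )
        rs = [ReactionSpec(s, t, f"k{i}", 100.0) for i, (s, t) in enumerate(edges)]
        m = build_from_reactions(rs, n)
        split = split_fast_slow(m, 1.0)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)
        expected = sorted(
            frozenset(c) for c in nx.connected_components(g) if len(c) >= 2
        )
        got = sorted(d.member_states for d in find_dgfrs(split))
        assert got == sorted(expected, key=min)

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_raising_epsilon_never_enlarges_dgfrs(self, data):
        n = data.draw(st.integers(3, 7))
        edges = data.draw(
            st.lists(
                st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(
                    lambda e: e[0] != e[1]
                ),
                min_size=1,
                max_size=10,
                unique=True,
            )
        )
        rs = [
            ReactionSpec(s, t, f"k{i}", data.draw(st.floats(1.0, 1e5)))
            for i, (s, t) in enumerate(edges)
        ]
        m = build_from_reactions(rs, n)
        lo = find_dgfrs(split_fast_slow(m, 10.0))
        hi = find_dgfrs(split_fast_slow(m, 1000.0))
        for d_hi in hi:
            assert any(d_hi.member_states <= d_lo.member_states for d_lo in lo)


class TestStrongComponents:
    def test_graph_g2_sc(self):
        m = _graph_model(G2_EDGES, fast_names={"b", "c", "d", "e", "f"})
        (dgfr,) = find_dgfrs(split_fast_slow(m, 100.0))
        comps = strong_components(dgfr)
        assert frozenset({1, 2, 3, 4}) in [c.member_states for c in comps]

    def test_six_state_single_sc(self, m6):
        (dgfr,) = find_dgfrs(split_fast_slow(m6, 100.0))
        comps = strong_components(dgfr)
        assert len(comps) == 1
        assert comps[0].member_states == frozenset({1, 2, 3, 4, 5})

    def test_fast_dag_gives_singletons(self):
        rs = [ReactionSpec(0, 1, "a", 1e4), ReactionSpec(1, 2, "b", 1e4)]
        m = build_from_reactions(rs, 3)
        (dgfr,) = find_dgfrs(split_fast_slow(m, 1.0))
        comps = strong_components(dgfr)
        assert sorted((c.member_states for c in comps), key=min) == [
            frozenset({0}), frozenset({1}), frozenset({2})
        ]

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_against_reachability_oracle(self, data):
        n = data.draw(st.integers(2, 8))
        edges = data.draw(
            st.lists(
                st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(
                    lambda e: e[0] != e[1]
                ),
                min_size=1,
                max_size=12,
                unique=True,
            )
        )
        dgfr = DGFR(frozenset(range(n)), edges)
        comps = strong_components(dgfr)
        # brute-force all-pairs reachability
        reach = np.eye(n, dtype=bool)
        for s, t in edges:
            reach[s, t] = True
        for k, i, j in itertools.product(range(n), repeat=3):
            if reach[i, k] and reach[k, j]:
                reach[i, j] = True
        for i, j in itertools.combinations(range(n), 2):
            same = any({i, j} <= c.member_states for c in comps)
            assert same == (reach[i, j] and reach[j, i])


class TestSinkClusters:
    def test_six_state_sink_cluster(self, m6):
        (dgfr,) = find_dgfrs(split_fast_slow(m6, 100.0))
        comps = classify_sink_clusters(dgfr, strong_components(dgfr))
        assert len(comps) == 1 and comps[0].is_sink_cluster

    def test_graph_g2_sink_cluster(self):
        m = _graph_model(G2_EDGES, fast_names={"b", "c", "d", "e", "f"})
        (dgfr,) = find_dgfrs(split_fast_slow(m, 100.0))
        comps = classify_sink_clusters(dgfr, strong_components(dgfr))
        big = next(c for c in comps if c.member_states == frozenset({1, 2, 3, 4}))
        assert big.is_sink_cluster

    def test_fast_chain(self):
        rs = [ReactionSpec(0, 1, "a", 1e4)]
        m = build_from_reactions(rs, 2)
        (dgfr,) = find_dgfrs(split_fast_slow(m, 1.0))
        comps = classify_sink_clusters(dgfr, strong_components(dgfr))
        flags = {min(c.member_states): c.is_sink_cluster for c in comps}
        assert flags == {0: False, 1: True}

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_definition_on_random_digraphs(self, data):
        n = data.draw(st.integers(2, 6))
        edges = data.draw(
            st.lists(
                st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(
                    lambda e: e[0] != e[1]
                ),
                min_size=1,
                max_size=10,
                unique=True,
            )
        )
        dgfr = DGFR(frozenset(range(n)), edges)
        comps = classify_sink_clusters(dgfr, strong_components(dgfr))
        for c in comps:
            expect = not any(
                s in c.member_states and t not in c.member_states for s, t in edges
            )
            assert c.is_sink_cluster == expect


class TestSlowStates:
    def test_six_state_no_slow_states(self, m6):
        assert slow_states(m6, 100.0) == set()

    def test_26_state_reduced_no_slow_states(self, m26):
        from statelump.reduction import reduce_model

        red, _ = reduce_model(m26, 1000.0, eliminate_threshold=1e-5)
        assert red.scheme.slow_states == []
        assert slow_states(red.model, 1000.0) == set()

    def test_isolated_tiny_rates_flagged(self):
        rs = [ReactionSpec(0, 1, "a", 1e-6), ReactionSpec(1, 0, "b", 1e-6)]
        m = build_from_reactions(rs, 2)
        assert slow_states(m, 100.0) == {0, 1}


class TestEliminateNegligible:
    def test_26_state_satellites(self, m26, traj26):
        removable = negligible_states(m26, traj26, 1e-5)
        # the two groups fed only by x21 and x22
        assert removable == {12, 13, 14, 25}

    def test_zero_threshold_no_eliminations(self, m26, traj26):
        assert negligible_states(m26, traj26, 0.0) == set()

    def test_toy_tiny_state_eliminated(self):
        # x1 -> x2 only; x3 has no inflow at all and stays exactly 0
        rs = [ReactionSpec(0, 1, "a", 1.0), ReactionSpec(2, 1, "b", 5.0)]
        m = build_from_reactions(rs, 3, x0=np.array([1.0, 0.0, 0.0]))
        traj = simulate(m, np.linspace(0, 5, 100))
        assert np.abs(traj.states[:, 2]).max() < 1e-9
        assert negligible_states(m, traj, 1e-9) == {2}

    def test_scheme_rewrite(self, m26, traj26):
        scheme = build_lumping_scheme(m26, 1000.0)
        out = eliminate_negligible(m26, scheme, traj26, 1e-5)
        assert set(out.eliminated) == {12, 13, 14, 25}
        out.check_partition(26)


class TestBuildLumpingScheme:
    def test_six_state(self, m6):
        scheme = build_lumping_scheme(m6, 100.0)
        assert len(scheme.lumps) == 1
        assert set(scheme.lumps[0].members) == {1, 2, 3, 4, 5}
        assert scheme.singletons == [0]
        assert scheme.slow_states == [] and scheme.eliminated == []

    def test_26_state_six_lumps(self, m26):
        scheme = build_lumping_scheme(m26, 1000.0, eliminate_threshold=1e-5)
        assert len(scheme.lumps) == 6
        members = {frozenset(l.members) for l in scheme.lumps}
        # the ambiguous fast connectors land with the returning sink
        assert frozenset({0, 1, 23}) in members  # x24 with x1
        assert frozenset({5, 7, 8, 24}) in members  # x25 with x8
        assert set(scheme.eliminated) == {12, 13, 14, 25}

    def test_no_fast_reactions_all_singletons(self, m6):
        scheme = build_lumping_scheme(m6, 1e6)
        assert scheme.lumps == []
        assert scheme.singletons == list(range(6))

    def test_partition_property(self, m26):
        scheme = build_lumping_scheme(m26, 1000.0, eliminate_threshold=1e-5)
        scheme.check_partition(26)

    def test_ambiguous_connector_without_return_kept_separate(self):
        # x1 -> {x2, x3} fast; x2, x3 sinks; no slow return path
        rs = [
            ReactionSpec(0, 1, "a", 1e4),
            ReactionSpec(0, 2, "b", 1e4),
            ReactionSpec(3, 0, "c", 1.0),
        ]
        m = build_from_reactions(rs, 4)
        scheme = build_lumping_scheme(m, 100.0)
        assert scheme.lumps == []
        assert 0 in scheme.singletons

    def test_ambiguous_connector_with_single_return_lumped(self):
        rs = [
            ReactionSpec(0, 1, "a", 1e4),
            ReactionSpec(0, 2, "b", 1e4),
            ReactionSpec(1, 0, "c", 1.0),  # slow return from sink x2 only
        ]
        m = build_from_reactions(rs, 3)
        scheme = build_lumping_scheme(m, 100.0)
        (lump,) = [l for l in scheme.lumps if 0 in l.members]
        assert set(lump.members) == {0, 1}
        assert lump.sink_cluster == frozenset({1})


def test_suggest_epsilon_six_state(m6):
    eps = suggest_epsilon(m6)
    assert 6.72 < eps < 240.0
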