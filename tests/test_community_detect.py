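"""Modularity, insertion gain and the first-level sweep.

The insertion-gain bookkeeping is checked against from-scratch Q
recomputation (and against networkx's independent modularity), and the
sweep is checked against exhaustive partition enumeration on tiny
graphs.
"""

import networkx as nx
import numpy as np
import pytest

from tfbsgroup.community_detect import (
    Partition,
    communities_of_size,
    louvain_level1,
    modularity,
    modularity_gain,
)
from tfbsgroup.lmer_graph import AdjacencyGraph

TRIANGLES = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]


def graph_of(n, edges):
    return AdjacencyGraph.from_edges(n, edges)


def random_graph(n, p, rng):
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return edges


def nx_modularity(n, edges, assignment):
    g = nx.Graph(edges)
    g.add_nodes_from(range(n))
    comms: dict[int, set[int]] = {}
    for v, c in enumerate(assignment):
        comms.setdefault(int(c), set()).add(v)
    return nx.community.modularity(g, comms.values())


class TestModularity:
    def test_one_community_is_zero(self):
        g = graph_of(6, TRIANGLES)
        assert modularity(g, np.zeros(6, dtype=int)) == pytest.approx(0.0)

    def test_singletons_of_two_triangles(self):
        g = graph_of(6, TRIANGLES)
        assert modularity(g, np.arange(6)) == pytest.approx(-1 / 6)

    def test_triangle_split_is_half(self):
        g = graph_of(6, TRIANGLES)
        assert modularity(g, np.array([0, 0, 0, 1, 1, 1])) == pytest.approx(0.5)

    def test_matches_networkx_on_random_partitions(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 16))
            edges = random_graph(n, 0.4, rng)
            if not edges:
                continue
            g = graph_of(n, edges)
            assignment = rng.integers(0, 3, size=n)
            assert modularity(g, assignment) == pytest.approx(
                nx_modularity(n, edges, assignment), abs=1e-12
            )

    def test_empty_graph_rejected(self):
        g = graph_of(3, [])
        with pytest.raises(ValueError):
            modularity(g, np.zeros(3, dtype=int))


class TestModularityGain:
    def test_single_edge_insertion(self):
        # A--B: singletons have Q = -0.5; merged, Q = 0; gain = 0.5
        g = graph_of(2, [(0, 1)])
        part = Partition(g)
        nb_count = 1
        part.remove(0, 0)  # node 0 is alone in its community: no internal links
        gain = modularity_gain(part, 0, 1, g)
        assert gain == pytest.approx(0.5)
        part.insert(0, 1, nb_count)
        assert part.q == pytest.approx(modularity(g, part))

    def test_gain_equals_recomputation_on_random_moves(self, rng):
        """Eq-3-style bookkeeping == from-scratch Q difference, 100 graphs."""
        checked = 0
        while checked < 100:
            n = int(rng.integers(4, 31))
            edges = random_graph(n, 0.3, rng)
            if not edges:
                continue
            g = graph_of(n, edges)
            part = Partition(g)
            # random legal sequence of moves, validating each gain
            for _ in range(15):
                node = int(rng.integers(n))
                target = int(rng.integers(n))
                if not part.members[target] or target == part.assignment[node]:
                    continue
                before = modularity(g, part)
                k_in_old = float(
                    np.count_nonzero(
                        part.assignment[g.neighbors(node)] == part.assignment[node]
                    )
                )
                c_old = part.remove(node, k_in_old)
                gain_target = modularity_gain(part, node, target, g)
                gain_back = modularity_gain(part, node, c_old, g)
                k_in_new = float(
                    np.count_nonzero(part.assignment[g.neighbors(node)] == target)
                )
                part.insert(node, target, k_in_new)
                after = modularity(g, part)
                assert after - before == pytest.approx(
                    gain_target - gain_back, abs=1e-9
                )
                assert part.q == pytest.approx(after, abs=1e-9)
            checked += 1


class TestLouvainLevel1:
    def test_two_triangles_found(self):
        g = graph_of(6, TRIANGLES)
        part = louvain_level1(g, seed=0)
        comms = {frozenset(c) for c in part.communities()}
        assert comms == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_bridged_triangles_stay_separate(self):
        g = graph_of(6, TRIANGLES + [(2, 3)])
        part = louvain_level1(g, seed=0)
        comms = {frozenset(c) for c in part.communities()}
        assert comms == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_deterministic_under_seed(self, rng):
        edges = random_graph(40, 0.15, rng)
        g = graph_of(40, edges)
        a = louvain_level1(g, seed=5)
        b = louvain_level1(g, seed=5)
        assert (a.assignment == b.assignment).all()

    def test_q_never_below_singletons_and_bookkeeping_exact(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 25))
            edges = random_graph(n, 0.3, rng)
            if not edges:
                continue
            g = graph_of(n, edges)
            part = louvain_level1(g, seed=1)
            q_singletons = modularity(g, np.arange(n))
            assert part.q >= q_singletons - 1e-12
            assert part.q == pytest.approx(modularity(g, part), abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_search_on_tiny_graphs(self, seed):
        """Level-1 result is a local optimum; on <=8 vertices its Q is
        compared with the global exhaustive-partition maximum."""
        rng = np.random.default_rng(seed + 700)
        n = int(rng.integers(4, 9))
        edges = random_graph(n, 0.45, rng)
        if not edges:
            edges = [(0, 1)]
        g = graph_of(n, edges)
        part = louvain_level1(g, seed=seed)
        # exhaustive max over all set partitions (Bell(8) = 4140)
        best = max(
            modularity(g, np.array(a)) for a in _set_partitions(n)
        )
        # the reached Q can never exceed the global optimum, and no
        # single-node move may improve it (local optimality)
        assert part.q <= best + 1e-12
        assert not _any_single_move_improves(g, part)


def _set_partitions(n):
    """All restricted-growth strings of length n (canonical partitions)."""
    def rec(prefix, k):
        if len(prefix) == n:
            yield prefix
            return
        for c in range(k + 1):
            yield from rec(prefix + [c], max(k, c + 1))
    yield from rec([0], 1)


def _any_single_move_improves(g, part, eps=1e-12):
    for node in range(g.n_vertices):
        base = modularity(g, part)
        current = part.assignment.copy()
        for target in set(part.assignment.tolist()) | {max(part.assignment) + 1}:
            if target == current[node]:
                continue
            trial = current.copy()
            trial[node] = target
            if modularity(g, trial) > base + eps:
                return True
    return False


class TestCommunitiesOfSize:
    def test_threshold_filtering(self):
        g = graph_of(6, TRIANGLES)
        part = louvain_level1(g, seed=0)
        assert len(communities_of_size(part, 0)) == 2
        assert len(communities_of_size(part, 3)) == 2
        assert communities_of_size(part, 4) == []
        assert communities_of_size(part, 100) == []

    def test_ordered_by_size_descending(self):
        g = graph_of(
            9, TRIANGLES + [(6, 7), (7, 8), (6, 8), (0, 6), (1, 7)]
        )
        part = louvain_level1(g, seed=0)
        sizes = [len(c) for c in communities_of_size(part, 1)]
        assert sizes == sorted(sizes, reverse=True)
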