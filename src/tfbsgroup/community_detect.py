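"""First-level modularity community detection (Louvain/BGLL phase 1).

Only the local-moving phase is run, to convergence, and its partition is
returned directly: candidate motif groups are the coarse communities of
the original l-mer graph, so the hierarchical aggregation phase of the
full algorithm is deliberately never entered.

Modularity of a partition (unweighted graph, A_ij in {0,1}):

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / 2m] * delta(C_i, C_j)

The sweep bookkeeping carries, per community, Sigma_in (internal edge
weight counted once per edge and doubled, i.e. sum_{i,j in C} A_ij) and
Sigma_tot (sum of member degrees); the insertion gain of an isolated
node is evaluated with the standard Louvain gain formula, which the test
suite checks against from-scratch Q recomputation.
"""

from __future__ import annotations

import numpy as np

from .lmer_graph import AdjacencyGraph

__all__ = [
    "Partition",
    "modularity",
    "modularity_gain",
    "louvain_level1",
    "communities_of_size",
]

#: moves are accepted only when the gain is strictly positive beyond
#: float noise
GAIN_EPS = 1e-12


class Partition:
    """Vertex -> community assignment with incremental Q bookkeeping."""

    def __init__(self, graph: AdjacencyGraph):
        if graph.m < 1:
            raise ValueError("modularity is undefined on a graph with no edges")
        self.graph = graph
        n = graph.n_vertices
        self.assignment = np.arange(n, dtype=np.int64)
        self.sigma_in = np.zeros(n, dtype=np.float64)
        self.sigma_tot = graph.degrees.astype(np.float64).copy()
        self.members: list[set[int]] = [{i} for i in range(n)]
        self.m = graph.m
        two_m = 2.0 * self.m
        self.q = float(-np.sum((graph.degrees / two_m) ** 2))

    def _comm_q(self, c: int) -> float:
        two_m = 2.0 * self.m
        return self.sigma_in[c] / two_m - (self.sigma_tot[c] / two_m) ** 2

    def remove(self, node: int, k_in: float) -> int:
        """Detach *node* from its community; returns the old community id."""
        c = int(self.assignment[node])
        k = float(self.graph.degrees[node])
        before = self._comm_q(c)
        self.sigma_in[c] -= 2.0 * k_in
        self.sigma_tot[c] -= k
        self.members[c].discard(node)
        self.q += self._comm_q(c) - before - (k / (2.0 * self.m)) ** 2
        self.assignment[node] = -1
        return c

    def insert(self, node: int, community: int, k_in: float) -> None:
        """Insert a detached *node* into *community*."""
        c = community
        k = float(self.graph.degrees[node])
        before = self._comm_q(c)
        self.sigma_in[c] += 2.0 * k_in
        self.sigma_tot[c] += k
        self.members[c].add(node)
        self.q += self._comm_q(c) - before + (k / (2.0 * self.m)) ** 2
        self.assignment[node] = c

    def communities(self) -> list[set[int]]:
        """All non-empty communities."""
        return [s for s in self.members if s]


def modularity(graph: AdjacencyGraph, partition: Partition | np.ndarray) -> float:
    """From-scratch modularity of a partition (the Q definition above)."""
    if graph.m < 1:
        raise ValueError("modularity is undefined on a graph with no edges")
    comm = partition.assignment if isinstance(partition, Partition) else np.asarray(partition)
    if len(comm) != graph.n_vertices or (comm < 0).any():
        raise ValueError("partition must assign every vertex to a community")
    u = np.repeat(np.arange(graph.n_vertices), np.diff(graph.indptr))
    v = graph.indices
    two_m = 2.0 * graph.m
    n_comm = int(comm.max()) + 1
    internal = np.bincount(comm[u], weights=(comm[u] == comm[v]), minlength=n_comm)
    sigma_tot = np.bincount(comm, weights=graph.degrees, minlength=n_comm)
    return float(np.sum(internal / two_m) - np.sum((sigma_tot / two_m) ** 2))


def _k_in(graph: AdjacencyGraph, partition: Partition, node: int, community: int) -> float:
    nb = graph.neighbors(node)
    if len(nb) == 0:
        return 0.0
    return float(np.count_nonzero(partition.assignment[nb] == community))


def modularity_gain(
    partition: Partition, node: int, community: int, graph: AdjacencyGraph
) -> float:
    """Insertion gain of a detached node into *community*.

    gain = [ (Sin + 2 k_in)/2m - ((Stot + k_i)/2m)^2 ]
         - [ Sin/2m - (Stot/2m)^2 - (k_i/2m)^2 ]

    The node must currently be detached (the Louvain move convention).
    """
    if int(partition.assignment[node]) != -1:
        raise ValueError("node must be detached before evaluating a gain")
    if community < 0 or community >= len(partition.members):
        raise ValueError(f"unknown community id {community}")
    two_m = 2.0 * partition.m
    k_i = float(graph.degrees[node])
    k_in = _k_in(graph, partition, node, community)
    s_in = partition.sigma_in[community]
    s_tot = partition.sigma_tot[community]
    after = (s_in + 2.0 * k_in) / two_m - ((s_tot + k_i) / two_m) ** 2
    before = s_in / two_m - (s_tot / two_m) ** 2 - (k_i / two_m) ** 2
    return after - before


def _tie_key(partition: Partition, c: int) -> float:
    return min(partition.members[c], default=float("inf"))


def louvain_level1(graph: AdjacencyGraph, seed: int = 0) -> Partition:
    """Run the local-moving phase to convergence and return its partition.

    Starting from singletons, vertices are visited in a freshly shuffled
    order each sweep (drawn from the seeded RNG); each vertex moves to
    the neighboring community of maximum positive gain, staying put when
    no move improves Q. Sweeps repeat until none moves a vertex. No
    aggregation step follows.
    """
    part = Partition(graph)
    rng = np.random.default_rng(seed)
    two_m2 = 2.0 * part.m * part.m
    while True:
        moved = False
        for node in rng.permutation(graph.n_vertices):
            node = int(node)
            nb = graph.neighbors(node)
            if len(nb) == 0:
                continue
            comms, counts = np.unique(part.assignment[nb], return_counts=True)
            link = dict(zip(comms.tolist(), counts.tolist()))
            c_old = part.remove(node, link.get(part.assignment[node], 0))
            k_i = float(graph.degrees[node])
            candidates = set(link) | {c_old}
            best_c, best_gain = c_old, -np.inf
            for c in sorted(candidates):
                gain = link.get(c, 0) / part.m - part.sigma_tot[c] * k_i / two_m2
                if gain > best_gain + GAIN_EPS:
                    best_c, best_gain = c, gain
                elif abs(gain - best_gain) <= GAIN_EPS and _tie_key(
                    part, c
                ) < _tie_key(part, best_c):
                    best_c = c
            gain_old = link.get(c_old, 0) / part.m - part.sigma_tot[c_old] * k_i / two_m2
            if best_c != c_old and best_gain - gain_old > GAIN_EPS:
                part.insert(node, best_c, link.get(best_c, 0))
                moved = True
            else:
                part.insert(node, c_old, link.get(c_old, 0))
        if not moved:
            break
    return part


def communities_of_size(partition: Partition, t_min: int) -> list[set[int]]:
    """Non-empty communities with at least ``t_min`` vertices.

    Ordered by size descending; ties broken by smallest member index so
    the downstream candidate order is deterministic.
    """
    comms = [s for s in partition.communities() if len(s) >= t_min]
    return sorted(comms, key=lambda s: (-len(s), min(s)))
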