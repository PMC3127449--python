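"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (double loops, full enumeration,
explicit BFS) and shares no code with the package's computation paths.
"""

from __future__ import annotations

import math
from collections import deque

import networkx as nx


def bfs_component(net: nx.Graph, source: int) -> set[int]:
    """Connected component of *source* by explicit breadth-first search."""
    seen = {source}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in net.adj[u]:
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return seen


def bruteforce_local_clustering(net: nx.Graph, i: int) -> float:
    """C_i by enumerating all neighbour pairs."""
    nbrs = list(net.adj[i])
    d = len(nbrs)
    if d <= 1:
        return 0.0
    n_i = 0
    for a in range(d):
        for b in range(a + 1, d):
            if net.has_edge(nbrs[a], nbrs[b]):
                n_i += 1
    return 2.0 * n_i / (d * (d - 1))


def bruteforce_global_clustering(net: nx.Graph) -> float:
    if net.number_of_nodes() == 0:
        return 0.0
    return sum(bruteforce_local_clustering(net, i) for i in net.nodes) / net.number_of_nodes()


def bruteforce_gwesp(net: nx.Graph, decay: float) -> float:
    """Term-by-term double loop over edges; shared partners by node scan."""
    total = 0.0
    for u, v in net.edges:
        shared = sum(1 for w in net.nodes if net.has_edge(u, w) and net.has_edge(v, w))
        if shared > 0:
            total += math.exp(decay) * (1.0 - (1.0 - math.exp(-decay)) ** shared)
    return total


def naive_stub_pairing(degrees, rng) -> nx.Graph:
    """Configuration model by explicitly sampling stub pairs without
    replacement, then dropping loops and collapsing duplicates."""
    stubs = [i for i, d in enumerate(degrees) for _ in range(d)]
    g = nx.empty_graph(len(degrees))
    while stubs:
        a = stubs.pop(int(rng.integers(len(stubs))))
        b = stubs.pop(int(rng.integers(len(stubs))))
        if a != b:
            g.add_edge(a, b)  # duplicate adds collapse in nx.Graph
    return g


def leaf_ancestor_descendants(tree) -> dict[int, int]:
    """Infective descendants of v = number of leaves having an internal node
    with infector v as an ancestor (walks parent pointers per leaf)."""
    counts = {node.individual: 0 for node in tree.leaves}
    for leaf in tree.leaves:
        ancestors_infectors = set()
        node = leaf.parent
        while node is not None:
            if node.kind == "internal":
                ancestors_infectors.add(node.infector)
            node = node.parent
        # a leaf never counts towards its own individual (the transmission
        # nodes on an individual's own timeline are ancestors of its leaf)
        ancestors_infectors.discard(leaf.individual)
        for v in ancestors_infectors:
            counts[v] += 1
    return counts


def prevalence_at(log, t: float, include_exposed: bool = True) -> int:
    """Infected count at time t by direct interval membership."""
    if include_exposed:
        starts = {e.individual: e.time for e in log.events if e.kind == "exposure"}
    else:
        starts = {e.individual: e.time for e in log.events if e.kind == "onset"}
    ends = {e.individual: e.time for e in log.events if e.kind == "recovery"}
    return sum(1 for u, s in starts.items() if s <= t < ends[u])
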