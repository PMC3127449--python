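"""Degree-preserving rewiring towards high or low clustering.

The sampler targets an exponential random graph density
``pi(Y) proportional to exp(theta * u(Y; tau))`` restricted to the graphs
with the same per-node degrees as the input, where ``u`` is the
geometrically weighted edgewise-shared-partner (gwesp) statistic

    u(Y; tau) = e**tau * sum_{i >= 1} [1 - (1 - e**-tau)**i] * EP_i(Y)

and ``EP_i`` counts the edges whose endpoints share exactly ``i`` partners.
Positive coefficients ``theta`` reward shared partners (triangles) and drive
clustering up; negative coefficients drive it down.

Sampling is Metropolis-Hastings over uniform double-edge swaps: two distinct
edges ``(a,b), (c,d)`` are drawn uniformly, one of the two rewirings
``{(a,d), (c,b)}`` or ``{(a,c), (b,d)}`` is picked with probability 1/2, and
a valid proposal (no loop, no duplicate edge) is accepted with probability
``min(1, exp(theta * delta_u))``.  Swaps preserve every node's degree
exactly, and the proposal distribution is symmetric, so the chain has
``pi`` as its stationary density.  Connectivity is *not* constrained: the
largest component may change size under rewiring.

:func:`rewire_network` runs a compiled kernel (see :mod:`epiclust._mh`);
the pure-Python operations in this module (:func:`gwesp_statistic`,
:func:`propose_swap`, :func:`delta_gwesp`, ...) define the semantics and are
cross-checked against brute-force oracles in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import _mh
from .networks import validate_network

__all__ = [
    "RewireConfig",
    "SwapProposal",
    "RewireStats",
    "shared_partners",
    "esp_histogram",
    "esp_weights",
    "gwesp_statistic",
    "propose_swap",
    "apply_swap",
    "delta_gwesp",
    "rewire_network",
]

logger = logging.getLogger(__name__)

LOG_INTERVAL = 10_000  # proposals between progress log lines (debug level)


@dataclass(frozen=True)
class RewireConfig:
    """Settings of the clustering-rewiring sampler.

    ``decay`` is the gwesp decay ``tau`` (default 0.2), ``coefficient`` the
    density coefficient ``theta`` (+5 for the high-clustering arm, -5 for the
    low-clustering arm), ``burnin`` the number of proposals to run (valid or
    not; default 5e5), and ``seed`` an optional integer seed for the kernel's
    random stream.
    """

    coefficient: float
    decay: float = 0.2
    burnin: int = 500_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.decay < 0:
            raise ValueError(f"decay must be >= 0, got {self.decay}")
        if self.burnin < 0:
            raise ValueError(f"burnin must be >= 0, got {self.burnin}")


@dataclass(frozen=True)
class SwapProposal:
    """A double-edge-swap proposal.

    ``edge_a = (a, b)`` and ``edge_b = (c, d)`` are the edges to remove;
    ``mode`` 0 proposes ``{(a, d), (c, b)}``, mode 1 proposes
    ``{(a, c), (b, d)}``.  ``valid`` is False when the rewiring would create
    a self-loop or duplicate an existing edge.
    """

    edge_a: tuple[int, int]
    edge_b: tuple[int, int]
    mode: int
    valid: bool

    @property
    def removed_edges(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.edge_a, self.edge_b)

    @property
    def added_edges(self) -> tuple[tuple[int, int], tuple[int, int]]:
        (a, b), (c, d) = self.edge_a, self.edge_b
        if self.mode == 0:
            return ((a, d), (c, b))
        return ((a, c), (b, d))


@dataclass(frozen=True)
class RewireStats:
    """Diagnostics of one rewiring run."""

    proposals: int
    valid: int
    accepted: int
    statistic: float  # gwesp value of the final state


def shared_partners(net: nx.Graph, i: int, j: int) -> int:
    """Number of common neighbours of nodes ``i`` and ``j``."""
    if i == j:
        raise ValueError("shared partners are defined for distinct nodes")
    if i not in net or j not in net:
        raise KeyError(f"nodes {i!r}, {j!r} must both be in the network")
    return len(set(net.adj[i]) & set(net.adj[j]))


def esp_histogram(net: nx.Graph) -> np.ndarray:
    """Edgewise shared-partner spectrum: entry ``i`` counts the edges whose
    endpoints share exactly ``i`` partners.  Sums to the edge count."""
    counts = [shared_partners(net, u, v) for u, v in net.edges]
    if not counts:
        return np.zeros(1, dtype=np.int64)
    return np.bincount(counts).astype(np.int64)

def esp_weights(decay: float, max_count: int) -> np.ndarray:
    """Per-edge gwesp weights ``w[s] = e**tau * (1 - (1 - e**-tau)**s)``.

    ``w[0] = 0``, so triangle-free graphs score 0, and ``w`` is strictly
    increasing in the shared-partner count ``s`` (for ``tau > 0``)."""
    s = np.arange(max_count + 1)
    return np.exp(decay) * (1.0 - (1.0 - np.exp(-decay)) ** s)


def gwesp_statistic(net: nx.Graph, decay: float) -> float:
    """Geometrically weighted edgewise-shared-partner statistic of *net*."""
    if decay < 0:
        raise ValueError(f"decay must be >= 0, got {decay}")
    ep = esp_histogram(net)
    return float(ep @ esp_weights(decay, len(ep) - 1))


def propose_swap(net: nx.Graph, rng: np.random.Generator) -> SwapProposal | None:
    """Draw a uniform double-edge-swap proposal; ``None`` if fewer than 2 edges.

    The proposal is marked invalid when a replacement edge would be a
    self-loop or duplicates an edge of the current graph.  Duplication is
    checked against the graph *before* removal, so a degenerate proposal
    that would merely recreate the removed edges (a no-op on the state) is
    also marked invalid; rejecting a no-op leaves the chain's law unchanged.
    Invalid proposals still count towards burn-in.
    """
    edges = list(net.edges)
    m = len(edges)
    if m < 2:
        return None
    i = int(rng.integers(m))
    j = int(rng.integers(m - 1))
    if j >= i:
        j += 1
    mode = int(rng.integers(2))
    proposal = SwapProposal(edge_a=edges[i], edge_b=edges[j], mode=mode, valid=True)
    (e, f), (g, h) = proposal.added_edges
    ok = e != f and g != h and not net.has_edge(e, f) and not net.has_edge(g, h)
    if ok:
        return proposal
    return SwapProposal(edge_a=edges[i], edge_b=edges[j], mode=mode, valid=False)


def apply_swap(net: nx.Graph, swap: SwapProposal) -> None:
    """Apply a valid swap to *net* in place."""
    if not swap.valid:
        raise ValueError("cannot apply an invalid swap proposal")
    for u, v in swap.removed_edges:
        net.remove_edge(u, v)
    for u, v in swap.added_edges:
        net.add_edge(u, v)


def _w(decay: float, s: int) -> float:
    if s <= 0:
        return 0.0
    return math.exp(decay) * (1.0 - (1.0 - math.exp(-decay)) ** s)


def _remove_delta(adj: dict, a: int, b: int, decay: float) -> float:
    delta = -_w(decay, len(adj[a] & adj[b]))
    adj[a].remove(b)
    adj[b].remove(a)
    for x, y in ((a, b), (b, a)):
        # pairs (x, z) that are edges and lost the shared partner y
        for z in adj[y]:
            if z in adj[x]:
                s_new = len(adj[x] & adj[z])
                delta += _w(decay, s_new) - _w(decay, s_new + 1)
    return delta


def _add_delta(adj: dict, a: int, b: int, decay: float) -> float:
    delta = 0.0
    for x, y in ((a, b), (b, a)):
        # pairs (x, z) that are edges and gain the shared partner y
        for z in adj[y]:
            if z in adj[x]:
                s_old = len(adj[x] & adj[z])
                delta += _w(decay, s_old + 1) - _w(decay, s_old)
    delta += _w(decay, len(adj[a] & adj[b]))
    adj[a].add(b)
    adj[b].add(a)
    return delta


def delta_gwesp(net: nx.Graph, swap: SwapProposal, decay: float) -> float:
    """Exact change in the gwesp statistic under *swap*.

    Computed incrementally: only pairs whose shared-partner count changes
    (those involving the four swap endpoints) are touched.  Equals
    ``gwesp_statistic(after) - gwesp_statistic(before)`` to floating-point
    accuracy.
    """
    if not swap.valid:
        raise ValueError("delta_gwesp requires a valid swap proposal")
    adj = {u: set(net.adj[u]) for u in net.nodes}
    (a, b), (c, d) = swap.removed_edges
    (e, f), (g, h) = swap.added_edges
    delta = _remove_delta(adj, a, b, decay)
    delta += _remove_delta(adj, c, d, decay)
    delta += _add_delta(adj, e, f, decay)
    delta += _add_delta(adj, g, h, decay)
    return delta


def _kernel_state(net: nx.Graph, decay: float):
    """Pack a network into the flat arrays the compiled kernel mutates."""
    nodes = sorted(net.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    m = net.number_of_edges()
    eu = np.empty(m, dtype=np.int32)
    ev = np.empty(m, dtype=np.int32)
    for k, (u, v) in enumerate(net.edges):
        eu[k] = index[u]
        ev[k] = index[v]
    A = np.zeros((n, n), dtype=np.bool_)
    A[eu, ev] = True
    A[ev, eu] = True
    sp = (A.astype(np.int32) @ A.astype(np.int32)).astype(np.int16)
    deg = A.sum(axis=1).astype(np.int32)
    start = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(deg, out=start[1:])
    nbr = np.empty(2 * m, dtype=np.int32)
    cur = np.zeros(n, dtype=np.int32)
    for k in range(m):
        a, b = eu[k], ev[k]
        nbr[start[a] + cur[a]] = b
        cur[a] += 1
        nbr[start[b] + cur[b]] = a
        cur[b] += 1
    w = esp_weights(decay, n)
    return nodes, eu, ev, A, sp, nbr, start, cur, w


def _clustering_from_state(A: np.ndarray, sp: np.ndarray) -> float:
    deg = A.sum(axis=1)
    two_n = (A * sp).sum(axis=1)  # = 2 * triangles through each node
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(deg > 1, two_n / (deg * (deg - 1.0)), 0.0)
    return float(c.mean())


def rewire_network(
    net: nx.Graph,
    config: RewireConfig,
    rng: np.random.Generator | None = None,
    return_stats: bool = False,
):
    """Rewire *net* for ``config.burnin`` proposals and return the final state.

    Every node's degree in the output equals its degree in the input exactly.
    The kernel seed comes from ``config.seed`` if set, otherwise from *rng*
    (or fresh entropy).  With ``return_stats=True`` a
    ``(network, RewireStats)`` pair is returned.
    """
    validate_network(net)
    m = net.number_of_edges()
    if m < 2 or config.burnin == 0:
        out = net.copy()
        stats = RewireStats(0, 0, 0, gwesp_statistic(out, config.decay))
        return (out, stats) if return_stats else out

    if config.seed is not None:
        seed_rng = np.random.default_rng(config.seed)
    elif rng is not None:
        seed_rng = rng
    else:
        seed_rng = np.random.default_rng()
    kernel_seed = int(seed_rng.integers(2**31 - 1))

    nodes, eu, ev, A, sp, nbr, start, cur, w = _kernel_state(net, config.decay)
    u0 = float(w[sp[eu, ev]].sum())

    theta = float(config.coefficient)
    n_valid = n_accepted = 0
    delta_sum = 0.0
    chunk = LOG_INTERVAL if logger.isEnabledFor(logging.DEBUG) else config.burnin
    done = 0
    seed_arg = kernel_seed
    while done < config.burnin:
        step = min(chunk, config.burnin - done)
        v, a, ds = _mh.mh_sweep(
            eu, ev, A, sp, nbr, start, cur, w, theta, step, seed_arg
        )
        seed_arg = -1  # continue the stream in later chunks
        n_valid += v
        n_accepted += a
        delta_sum += ds
        done += step
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "rewire theta=%+g: %d/%d proposals, acceptance %.3f, "
                "statistic %.2f, clustering %.4f",
                theta,
                done,
                config.burnin,
                n_accepted / max(n_valid, 1),
                u0 + delta_sum,
                _clustering_from_state(A, sp),
            )

    out = nx.Graph()
    out.add_nodes_from(nodes)
    out.add_edges_from((nodes[int(a)], nodes[int(b)]) for a, b in zip(eu, ev))
    stats = RewireStats(config.burnin, n_valid, n_accepted, u0 + delta_sum)
    return (out, stats) if return_stats else out
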