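"""Random contact-network models and clustering diagnostics.

A contact network is an undirected simple graph: nodes are hosts, edges are
potential transmission routes.  Throughout the package networks are plain
:class:`networkx.Graph` objects with integer node labels -- no self-loops,
no parallel edges, binary adjacency.  :func:`validate_network` asserts those
structural invariants and is used liberally in the test suite.

Two generative models are provided:

* a Bernoulli (Erdos-Renyi) graph, built by drawing the total edge count
  ``|Y| ~ Binomial(N(N-1)/2, p)`` and then placing ``|Y|`` distinct edges
  uniformly at random;
* an approximate power-law graph with ``P(d = k) proportional to k**-alpha``,
  assembled from a sampled degree sequence by uniform stub pairing
  (configuration model) followed by loop removal and multi-edge collapse.

Clustering is measured with the local coefficient
``C_i = 2 n_i / (d_i (d_i - 1))`` (``n_i`` = edges among neighbours of ``i``,
``C_i = 0`` when ``d_i <= 1``) and its mean over all nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "BernoulliParams",
    "PowerLawParams",
    "validate_network",
    "sample_bernoulli",
    "sample_power_law_degrees",
    "assemble_configuration_model",
    "sample_power_law",
    "largest_component",
    "local_clustering",
    "global_clustering",
    "degree_histogram",
    "read_edgelist",
    "write_edgelist",
    "read_graphml",
    "write_graphml",
    "network_from_config",
]


@dataclass(frozen=True)
class BernoulliParams:
    """Parameters of the Bernoulli (Erdos-Renyi) network model."""

    n_nodes: int
    edge_prob: float

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError(f"n_nodes must be >= 2, got {self.n_nodes}")
        if not 0.0 <= self.edge_prob <= 1.0:
            raise ValueError(f"edge_prob must lie in [0, 1], got {self.edge_prob}")


@dataclass(frozen=True)
class PowerLawParams:
    """Parameters of the approximate power-law network model.

    Degrees are supported on ``k = 1 .. max_degree``; the default cutoff
    ``max_degree = n_nodes - 1`` is the largest degree a simple graph admits.
    A cutoff is required because for exponents below 2 the raw power law has
    a divergent mean.
    """

    n_nodes: int
    exponent: float
    max_degree: int | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError(f"n_nodes must be >= 2, got {self.n_nodes}")
        if not self.exponent > 0:
            raise ValueError(f"exponent must be positive, got {self.exponent}")
        kmax = self.resolved_max_degree
        if not 1 <= kmax <= self.n_nodes - 1:
            raise ValueError(f"max_degree must lie in [1, n_nodes - 1], got {kmax}")

    @property
    def resolved_max_degree(self) -> int:
        return self.n_nodes - 1 if self.max_degree is None else self.max_degree


def validate_network(net: nx.Graph) -> None:
    """Raise ``ValueError`` if *net* is not a valid contact network."""
    if net.is_directed() or net.is_multigraph():
        raise ValueError("contact networks are undirected simple graphs")
    for u in net.nodes:
        if not isinstance(u, (int, np.integer)):
            raise ValueError(f"node labels must be integers, got {u!r}")
    loops = list(nx.selfloop_edges(net))
    if loops:
        raise ValueError(f"self-loops are not allowed: {loops[:5]}")
    if sum(d for _, d in net.degree()) != 2 * net.number_of_edges():
        raise ValueError("degree sum does not equal twice the edge count")


def sample_bernoulli(params: BernoulliParams, rng: np.random.Generator) -> nx.Graph:
    """Draw a Bernoulli graph: edge count binomial, edges uniform without replacement."""
    n = params.n_nodes
    n_pairs = n * (n - 1) // 2
    m = int(rng.binomial(n_pairs, params.edge_prob))
    g = nx.empty_graph(n)
    if m > 0:
        iu, iv = np.triu_indices(n, k=1)
        chosen = rng.choice(n_pairs, size=m, replace=False)
        g.add_edges_from(zip(iu[chosen].tolist(), iv[chosen].tolist()))
    return g


def sample_power_law_degrees(
    params: PowerLawParams, rng: np.random.Generator
) -> np.ndarray:
    """Sample an even-sum degree sequence with ``P(d = k) proportional to k**-alpha``.

    Degrees are drawn i.i.d. on ``1 .. max_degree``.  If the total is odd one
    uniformly chosen node has its degree redrawn until the total is even, so
    the sequence can always be realised by stub pairing.
    """
    n = params.n_nodes
    kmax = params.resolved_max_degree
    k = np.arange(1, kmax + 1)
    pmf = k.astype(float) ** -params.exponent
    pmf /= pmf.sum()
    degrees = rng.choice(k, size=n, p=pmf)
    if degrees.sum() % 2 == 1:
        j = int(rng.integers(n))
        while degrees.sum() % 2 == 1:
            degrees[j] = rng.choice(k, p=pmf)
    return degrees.astype(np.int64)


def assemble_configuration_model(degrees, rng: np.random.Generator) -> nx.Graph:
    """Pair edge stubs uniformly, then drop loops and collapse parallel edges.

    The realised degree of every node is at most its requested degree (the
    cleanup step only removes edge endpoints, never adds them).
    """
    degrees = [int(d) for d in degrees]
    if any(d < 0 for d in degrees):
        raise ValueError("degrees must be non-negative")
    if sum(degrees) % 2 == 1:
        raise ValueError("degree sum must be even to pair all stubs")
    multigraph = nx.configuration_model(degrees, seed=rng)
    g = nx.Graph(multigraph)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def sample_power_law(params: PowerLawParams, rng: np.random.Generator) -> nx.Graph:
    """Sample degrees and assemble the approximate power-law graph."""
    return assemble_configuration_model(sample_power_law_degrees(params, rng), rng)


def largest_component(net: nx.Graph) -> nx.Graph:
    """Node-induced subgraph on the largest connected component.

    Original node labels are retained.  Ties on size are broken in favour of
    the component containing the smallest node label, so the result is
    deterministic.
    """
    if net.number_of_nodes() == 0:
        return net.copy()
    components = nx.connected_components(net)
    best = min(components, key=lambda c: (-len(c), min(c)))
    return net.subgraph(best).copy()


def local_clustering(net: nx.Graph, node: int) -> float:
    """Local clustering coefficient ``C_i``; 0 for nodes of degree 0 or 1."""
    if node not in net:
        raise KeyError(f"node {node!r} not in network")
    return float(nx.clustering(net, node))


def global_clustering(net: nx.Graph) -> float:
    """Mean of the local clustering coefficients over *all* nodes.

    Nodes of degree 0 or 1 contribute 0 to the mean.  The empty graph returns
    0 by convention.
    """
    if net.number_of_nodes() == 0:
        return 0.0
    return float(nx.average_clustering(net, count_zeros=True))


def degree_histogram(net: nx.Graph) -> np.ndarray:
    """Entry ``k`` counts the nodes of degree ``k``, from 0 to the max degree."""
    return np.asarray(nx.degree_histogram(net), dtype=np.int64)


# ---------------------------------------------------------------------------
# file formats


def write_edgelist(net: nx.Graph, path) -> None:
    """Two tab-separated integer columns, one undirected edge per line,
    smaller label first, lines sorted."""
    edges = sorted((min(u, v), max(u, v)) for u, v in net.edges)
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_edgelist(path, n_nodes: int | None = None) -> nx.Graph:
    """Read the tab-separated edge-list format.

    Edge lists cannot represent isolated nodes; pass ``n_nodes`` to pad the
    node set to ``0 .. n_nodes - 1``.
    """
    g = nx.Graph()
    if n_nodes is not None:
        g.add_nodes_from(range(n_nodes))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            u, v = line.split("\t")
            g.add_edge(int(u), int(v))
    return g


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path, node_type=int)
    return nx.Graph(g)


def network_from_config(config: dict, rng: np.random.Generator) -> nx.Graph:
    """Build a network from a config mapping.

    Keys: ``model`` in {"bernoulli", "powerlaw"}, ``n_nodes``, and
    ``edge_prob`` (bernoulli) or ``exponent`` / optional ``max_degree``
    (powerlaw).
    """
    model = config["model"]
    if model == "bernoulli":
        return sample_bernoulli(
            BernoulliParams(int(config["n_nodes"]), float(config["edge_prob"])), rng
        )
    if model == "powerlaw":
        return sample_power_law(
            PowerLawParams(
                int(config["n_nodes"]),
                float(config["exponent"]),
                config.get("max_degree"),
            ),
            rng,
        )
    raise ValueError(f"unknown network model {model!r}")
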