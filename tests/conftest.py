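from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from epiclust.networks import BernoulliParams, largest_component, sample_bernoulli
from epiclust.seir import EXPOSURE, ONSET, RECOVERY, EpidemicParams, Event, EventLog
from epiclust.seir import simulate_conditioned


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def k4_minus_edge():
    g = nx.complete_graph(4)
    g.remove_edge(0, 1)
    return g


@pytest.fixture
def single_individual_log():
    """One host: exposed at 0, infectious at 1, recovered at 3.1."""
    return EventLog(
        index_node=0,
        events=[
            Event(0.0, EXPOSURE, 0, None),
            Event(1.0, ONSET, 0, None),
            Event(3.1, RECOVERY, 0, None),
        ],
    )


@pytest.fixture
def two_individual_log():
    """Host 0 exposed at 0, infects host 1 at 1.3, recovers at 3.1;
    host 1 becomes infectious at 2.0 and recovers at 4.0."""
    return EventLog(
        index_node=0,
        events=[
            Event(0.0, EXPOSURE, 0, None),
            Event(1.0, ONSET, 0, None),
            Event(1.3, EXPOSURE, 1, 0),
            Event(2.0, ONSET, 1, None),
            Event(3.1, RECOVERY, 0, None),
            Event(4.0, RECOVERY, 1, None),
        ],
    )


@pytest.fixture
def five_host_chain_log():
    """A five-host transmission chain 1 -> 2 -> 3 -> 4 -> 5 whose tree has
    exactly one cherry: the leaves of hosts 4 and 5 hang off the internal
    node where 4 infects 5."""
    return EventLog(
        index_node=1,
        events=[
            Event(0.0, EXPOSURE, 1, None),
            Event(0.5, ONSET, 1, None),
            Event(1.3, EXPOSURE, 2, 1),
            Event(1.8, ONSET, 2, None),
            Event(2.1, EXPOSURE, 3, 2),
            Event(2.9, ONSET, 3, None),
            Event(3.1, RECOVERY, 1, None),
            Event(3.4, EXPOSURE, 4, 3),
            Event(3.9, RECOVERY, 2, None),
            Event(4.0, ONSET, 4, None),
            Event(4.6, EXPOSURE, 5, 4),
            Event(4.9, RECOVERY, 3, None),
            Event(5.0, ONSET, 5, None),
            Event(5.2, RECOVERY, 4, None),
            Event(6.2, RECOVERY, 5, None),
        ],
    )


@pytest.fixture(scope="session")
def bernoulli_giant():
    """Largest component of one Bernoulli (N=500, p=0.014) draw."""
    rng = np.random.default_rng(7)
    net = sample_bernoulli(BernoulliParams(500, 0.014), rng)
    return largest_component(net)


@pytest.fixture(scope="session")
def simulated_logs(bernoulli_giant):
    """Ten conditioned SEIR runs on the Bernoulli giant component."""
    rng = np.random.default_rng(99)
    params = EpidemicParams()
    nodes = sorted(bernoulli_giant)
    logs = []
    for _ in range(10):
        index = nodes[int(rng.integers(len(nodes)))]
        log, _ = simulate_conditioned(bernoulli_giant, params, index, rng)
        logs.append(log)
    return logs
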