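"""Event-driven stochastic SEIR epidemics on contact networks.

The outbreak starts from a single index node exposed at time 0.  An exposed
node becomes infectious after a gamma-distributed latent period (shape
``k_E``, scale ``theta_E``) and recovers after a gamma-distributed
infectious period (shape ``k_I``, scale ``theta_I``).  While infectious, a
node transmits along each edge to a susceptible neighbour according to a
Poisson process with rate ``beta``; since re-infection is impossible, only
the first potential transmission per infectious-susceptible pair matters,
so a single exponential first-contact time is drawn per pair.  Recovered
nodes play no further part.  The process stops when no exposed or
infectious nodes remain.

Defaults follow the simulation study this package reproduces:
``beta = 0.1`` per day, ``k_E = k_I = 1``, ``theta_E = theta_I = 3`` days,
and outbreaks conditioned on infecting at least 20 nodes.

The raw record of a run is an :class:`EventLog`: a time-ordered list of
exposure / onset / recovery events with infector attribution, from which the
transmission tree and all summaries are derived.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np

from .networks import largest_component

__all__ = [
    "EXPOSURE",
    "ONSET",
    "RECOVERY",
    "EpidemicParams",
    "Event",
    "EventLog",
    "ConditioningError",
    "PairingError",
    "validate_event_log",
    "draw_gamma_period",
    "simulate_seir",
    "simulate_conditioned",
    "paired_epidemics",
]

EXPOSURE = "exposure"
ONSET = "onset"
RECOVERY = "recovery"

_KIND_ORDER = {EXPOSURE: 0, ONSET: 1, RECOVERY: 2}

_SUSCEPTIBLE, _EXPOSED, _INFECTIOUS, _REMOVED = 0, 1, 2, 3


@dataclass(frozen=True)
class EpidemicParams:
    """SEIR parameters: rates per day, periods in days."""

    beta: float = 0.1
    k_E: float = 1.0
    theta_E: float = 3.0
    k_I: float = 1.0
    theta_I: float = 3.0
    min_outbreak: int = 20

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        for name in ("k_E", "theta_E", "k_I", "theta_I"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.min_outbreak < 1:
            raise ValueError(f"min_outbreak must be >= 1, got {self.min_outbreak}")


class Event(NamedTuple):
    time: float
    kind: str  # one of EXPOSURE, ONSET, RECOVERY
    individual: int
    infector: int | None  # set only on non-index exposures


@dataclass
class EventLog:
    """Time-ordered epidemic record; the index node is exposed at time 0."""

    index_node: int
    events: list[Event] = field(default_factory=list)

    @property
    def final_size(self) -> int:
        return sum(1 for e in self.events if e.kind == EXPOSURE)

    @property
    def last_recovery(self) -> float:
        return max(e.time for e in self.events if e.kind == RECOVERY)

    def exposure_times(self) -> dict[int, float]:
        return {e.individual: e.time for e in self.events if e.kind == EXPOSURE}

    def recovery_times(self) -> dict[int, float]:
        return {e.individual: e.time for e in self.events if e.kind == RECOVERY}

    def to_tsv(self, path) -> None:
        """Serialize as TSV with header ``time  kind  individual  infector``."""
        with open(path, "w") as fh:
            fh.write("time\tkind\tindividual\tinfector\n")
            for e in self.events:
                infector = "" if e.infector is None else str(e.infector)
                fh.write(f"{e.time!r}\t{e.kind}\t{e.individual}\t{infector}\n")

    @classmethod
    def from_tsv(cls, path) -> "EventLog":
        events = []
        with open(path) as fh:
            header = fh.readline()
            if header.strip().split("\t") != ["time", "kind", "individual", "infector"]:
                raise ValueError(f"unexpected event-log header: {header!r}")
            for line in fh:
                t, kind, ind, infector = line.rstrip("\n").split("\t")
                events.append(
                    Event(float(t), kind, int(ind), int(infector) if infector else None)
                )
        index = next(e.individual for e in events if e.kind == EXPOSURE)
        return cls(index_node=index, events=events)


class ConditioningError(RuntimeError):
    """No run from the given index reached the outbreak threshold."""

    def __init__(self, index: int, attempts: int):
        super().__init__(
            f"no outbreak from index node {index} reached the threshold "
            f"in {attempts} attempts"
        )
        self.index = index
        self.attempts = attempts


class PairingError(RuntimeError):
    """A paired epidemic could not be set up or conditioned."""


def validate_event_log(log: EventLog) -> None:
    """Raise ``ValueError`` if *log* violates the epidemic-record invariants."""
    times = [e.time for e in log.events]
    if times != sorted(times):
        raise ValueError("events are not time-ordered")
    per_kind: dict[str, dict[int, float]] = {EXPOSURE: {}, ONSET: {}, RECOVERY: {}}
    infectors: dict[int, int | None] = {}
    for e in log.events:
        if e.kind not in per_kind:
            raise ValueError(f"unknown event kind {e.kind!r}")
        if e.individual in per_kind[e.kind]:
            raise ValueError(f"duplicate {e.kind} for individual {e.individual}")
        per_kind[e.kind][e.individual] = e.time
        if e.kind == EXPOSURE:
            infectors[e.individual] = e.infector
        elif e.infector is not None:
            raise ValueError(f"{e.kind} events must not carry an infector")
    exposed = per_kind[EXPOSURE]
    if set(per_kind[ONSET]) != set(exposed) or set(per_kind[RECOVERY]) != set(exposed):
        raise ValueError("every exposed individual must have onset and recovery")
    if log.index_node not in exposed:
        raise ValueError("index node never exposed")
    if exposed[log.index_node] != 0.0:
        raise ValueError("index exposure must occur at time 0")
    if infectors[log.index_node] is not None:
        raise ValueError("index exposure must have no infector")
    for u, t_exp in exposed.items():
        if not t_exp < per_kind[ONSET][u] < per_kind[RECOVERY][u]:
            raise ValueError(f"individual {u}: need exposure < onset < recovery")
        v = infectors[u]
        if u == log.index_node:
            continue
        if v is None:
            raise ValueError(f"non-index exposure of {u} must name an infector")
        if v not in exposed:
            raise ValueError(f"infector {v} of {u} was never infected")
        if not per_kind[ONSET][v] <= t_exp < per_kind[RECOVERY][v]:
            raise ValueError(f"infector {v} was not infectious when exposing {u}")


def draw_gamma_period(shape: float, scale: float, rng: np.random.Generator) -> float:
    """A gamma waiting time with mean ``shape * scale`` (days)."""
    if not shape > 0 or not scale > 0:
        raise ValueError(f"gamma shape and scale must be positive, got {shape}, {scale}")
    return float(rng.gamma(shape, scale))


def simulate_seir(
    net: nx.Graph,
    params: EpidemicParams,
    index: int,
    rng: np.random.Generator,
) -> EventLog:
    """Run one SEIR epidemic from *index*; return the full event log.

    Deterministic given (network, parameters, index, generator state): the
    event queue breaks ties on (time, kind order, insertion order).
    """
    if index not in net:
        raise KeyError(f"index node {index!r} not in network")
    status = {u: _SUSCEPTIBLE for u in net.nodes}
    log = EventLog(index_node=index)
    heap: list[tuple[float, int, int, int | None]] = []
    counter = 0  # insertion order; stabilises heap ties

    def push(time: float, kind: str, individual: int, infector: int | None) -> None:
        nonlocal counter
        heapq.heappush(heap, (time, _KIND_ORDER[kind], counter, individual, infector))
        counter += 1

    push(0.0, EXPOSURE, index, None)
    while heap:
        time, kind_order, _, u, infector = heapq.heappop(heap)
        if kind_order == _KIND_ORDER[EXPOSURE]:
            if status[u] != _SUSCEPTIBLE:
                continue  # a stale transmission attempt; u was exposed earlier
            status[u] = _EXPOSED
            log.events.append(Event(time, EXPOSURE, u, infector))
            push(time + draw_gamma_period(params.k_E, params.theta_E, rng), ONSET, u, None)
        elif kind_order == _KIND_ORDER[ONSET]:
            status[u] = _INFECTIOUS
            log.events.append(Event(time, ONSET, u, None))
            period = draw_gamma_period(params.k_I, params.theta_I, rng)
            push(time + period, RECOVERY, u, None)
            if params.beta > 0:
                for nb in net.adj[u]:
                    if status[nb] == _SUSCEPTIBLE:
                        contact = time + rng.exponential(1.0 / params.beta)
                        if contact < time + period:
                            push(contact, EXPOSURE, nb, u)
        else:
            status[u] = _REMOVED
            log.events.append(Event(time, RECOVERY, u, None))
    return log


def simulate_conditioned(
    net: nx.Graph,
    params: EpidemicParams,
    index: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> tuple[EventLog, int]:
    """Re-run the epidemic (index fixed, fresh randomness) until the final
    size reaches ``params.min_outbreak``; return (log, attempts used)."""
    if max_attempts < 1:
        raise ValueError(f"max_attempts must be >= 1, got {max_attempts}")
    for attempt in range(1, max_attempts + 1):
        log = simulate_seir(net, params, index, rng)
        if log.final_size >= params.min_outbreak:
            return log, attempt
    raise ConditioningError(index, max_attempts)


def paired_epidemics(
    net_hi: nx.Graph,
    net_lo: nx.Graph,
    params: EpidemicParams,
    rng: np.random.Generator,
    max_attempts: int = 1000,
    index_redraws: int = 20,
) -> tuple[EventLog, EventLog]:
    """Conditioned epidemics on the paired networks from a shared index node.

    The index is drawn uniformly from the node ids that lie in the largest
    connected component of *both* networks.  If conditioning fails on either
    arm, a new index is drawn and both arms restart (up to ``index_redraws``
    times).
    """
    shared = set(largest_component(net_hi)) & set(largest_component(net_lo))
    if not shared:
        raise PairingError(
            "the largest components of the two networks share no node ids"
        )
    candidates = sorted(shared)
    for _ in range(index_redraws):
        index = candidates[int(rng.integers(len(candidates)))]
        try:
            log_hi, _ = simulate_conditioned(net_hi, params, index, rng, max_attempts)
            log_lo, _ = simulate_conditioned(net_lo, params, index, rng, max_attempts)
        except ConditioningError:
            continue
        return log_hi, log_lo
    raise PairingError(
        f"conditioning failed from {index_redraws} candidate index nodes"
    )
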