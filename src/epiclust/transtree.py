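"""Transmission trees and their topological / temporal statistics.

A transmission tree is a timed rooted tree derived from an epidemic event
log.  Its nodes are of three kinds:

* the **root** ``(t_0, u_0)`` -- the spontaneous infection of the index;
* **internal** nodes ``(t, u, v)`` -- individual ``u`` infected by ``v`` at
  time ``t``;
* **leaves** ``(t, u)`` -- the recovery of individual ``u``.

Each infected individual has a timeline: their own infection event, the
transmissions they cause (in time order), and their recovery.  Branches
connect consecutive events on a timeline, so an internal node ``(t, u, v)``
has two children -- the continuation of the infector ``v``'s timeline and
the start of the infectee ``u``'s -- while the root has one child and leaves
none.  A tree over ``L`` infected individuals therefore has ``L - 1``
internal nodes and ``2L - 1`` branches, and the branch lengths of the tree
sum to the total time its individuals spent infected.

Statistics: mean branch length between internal nodes (mean time between
successive secondary infections), mean length of branches adjacent to a
leaf (mean time from last secondary infection to removal), per-individual
secondary-infection and infective-descendant counts, and the number of
cherries (pairs of leaves adjacent to a common internal node).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .seir import EXPOSURE, RECOVERY, EventLog, validate_event_log

__all__ = [
    "TreeNode",
    "TransmissionTree",
    "build_tree",
    "validate_tree",
    "branch_length_summaries",
    "count_cherries",
    "max_cherries",
    "secondary_infection_counts",
    "infective_descendant_counts",
    "write_newick",
    "write_tree_tsv",
]

ROOT = "root"
INTERNAL = "internal"
LEAF = "leaf"


@dataclass
class TreeNode:
    """One node of a transmission tree.

    ``individual`` is the infectee for root/internal nodes and the recovered
    individual for leaves; ``infector`` is set on internal nodes only.
    ``branch_length`` is the length of the branch to the parent (``None`` at
    the root).
    """

    time: float
    kind: str  # ROOT, INTERNAL or LEAF
    individual: int
    infector: int | None = None
    parent: "TreeNode | None" = None
    branch_length: float | None = None
    children: "list[TreeNode]" = field(default_factory=list)

    def __repr__(self) -> str:  # keep recursion out of reprs
        return (
            f"TreeNode({self.time}, {self.kind}, u={self.individual}, "
            f"v={self.infector})"
        )


@dataclass
class TransmissionTree:
    root: TreeNode
    internals: list[TreeNode]
    leaves: list[TreeNode]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def nodes(self):
        yield self.root
        yield from self.internals
        yield from self.leaves

    def branches(self):
        """All (parent, child) links."""
        for node in self.nodes():
            for child in node.children:
                yield node, child


def build_tree(log: EventLog) -> TransmissionTree:
    """Build the transmission tree of a (valid) epidemic event log."""
    validate_event_log(log)
    entry: dict[int, TreeNode] = {}
    caused: dict[int, list[TreeNode]] = {}
    leaf_of: dict[int, TreeNode] = {}
    internals: list[TreeNode] = []
    leaves: list[TreeNode] = []
    root: TreeNode | None = None
    for e in log.events:  # already time-ordered
        if e.kind == EXPOSURE:
            if e.individual == log.index_node:
                node = TreeNode(e.time, ROOT, e.individual)
                root = node
            else:
                node = TreeNode(e.time, INTERNAL, e.individual, infector=e.infector)
                internals.append(node)
                caused.setdefault(e.infector, []).append(node)
            entry[e.individual] = node
        elif e.kind == RECOVERY:
            node = TreeNode(e.time, LEAF, e.individual)
            leaf_of[e.individual] = node
            leaves.append(node)
    assert root is not None
    for u, first in entry.items():
        timeline = [first, *caused.get(u, []), leaf_of[u]]
        for parent, child in zip(timeline, timeline[1:]):
            child.parent = parent
            child.branch_length = child.time - parent.time
            parent.children.append(child)
    return TransmissionTree(root=root, internals=internals, leaves=leaves)


def validate_tree(tree: TransmissionTree) -> None:
    """Raise ``ValueError`` on violation of the structural invariants."""
    if len(tree.internals) != len(tree.leaves) - 1:
        raise ValueError("need |internals| = |leaves| - 1")
    n_branches = sum(1 for _ in tree.branches())
    if n_branches != 2 * len(tree.leaves) - 1:
        raise ValueError("need 2|leaves| - 1 branches")
    if len(tree.root.children) != 1 and len(tree.leaves) > 0:
        raise ValueError("the root must have exactly one child")
    for node in tree.internals:
        if len(node.children) != 2:
            raise ValueError(f"internal node {node} must have two children")
    for parent, child in tree.branches():
        if not child.time > parent.time:
            raise ValueError(f"child {child} not later than parent {parent}")
        if not math.isclose(
            child.branch_length, child.time - parent.time, abs_tol=1e-12
        ):
            raise ValueError(f"branch length mismatch at {child}")


def branch_length_summaries(tree: TransmissionTree) -> tuple[float, float]:
    """(mean internal-branch length, mean external-branch length), in days.

    Branches are classified by their child endpoint: internal-child branches
    lie between transmission events, leaf-child branches are adjacent to a
    recovery.  A tree with no internal nodes (single individual) has no
    internal branches; ``nan`` marks the undefined mean.
    """
    internal = [n.branch_length for n in tree.internals]
    external = [n.branch_length for n in tree.leaves]
    mean_internal = sum(internal) / len(internal) if internal else math.nan
    mean_external = sum(external) / len(external)
    return mean_internal, mean_external


def count_cherries(tree: TransmissionTree) -> int:
    """Internal nodes both of whose child branches terminate in leaves."""
    return sum(
        1
        for node in tree.internals
        if all(child.kind == LEAF for child in node.children)
    )


def max_cherries(n_leaves: int) -> int:
    """Largest possible cherry count of a tree with ``n_leaves`` leaves."""
    if n_leaves < 1:
        raise ValueError(f"a tree has at least one leaf, got {n_leaves}")
    return n_leaves // 2


def secondary_infection_counts(tree: TransmissionTree) -> dict[int, int]:
    """Secondary infections caused by each infected individual (zeros kept)."""
    counts = {node.individual: 0 for node in tree.leaves}
    for node in tree.internals:
        counts[node.infector] += 1
    return counts


def infective_descendant_counts(tree: TransmissionTree) -> dict[int, int]:
    """Recursive total of infections downstream of each individual.

    Descendants of ``v`` are the individuals ``v`` infected, those they
    infected, and so on; the index's count is ``|leaves| - 1``.
    """
    infected_by: dict[int, list[int]] = {node.individual: [] for node in tree.leaves}
    for node in tree.internals:
        infected_by[node.infector].append(node.individual)
    counts: dict[int, int] = {}
    # post-order over the infection tree, iteratively (outbreak chains can be
    # long enough to trouble Python's recursion limit)
    stack: list[tuple[int, bool]] = [(tree.root.individual, False)]
    while stack:
        v, expanded = stack.pop()
        if expanded:
            counts[v] = sum(1 + counts[u] for u in infected_by[v])
        else:
            stack.append((v, True))
            stack.extend((u, False) for u in infected_by[v])
    return counts


def _newick_label(node: TreeNode) -> str:
    return str(node.individual) if node.kind == LEAF else ""


def _newick(node: TreeNode) -> str:
    length = "" if node.branch_length is None else f":{node.branch_length:.10g}"
    if not node.children:
        return f"{_newick_label(node)}{length}"
    inner = ",".join(_newick(child) for child in node.children)
    return f"({inner}){_newick_label(node)}{length}"


def write_newick(tree: TransmissionTree, path=None) -> str:
    """Rooted Newick string; leaf labels are individual ids, branch lengths
    are the timeline interval lengths.  Optionally written to *path*."""
    text = _newick(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def write_tree_tsv(tree: TransmissionTree, path) -> None:
    """TSV mirror of the node triples: node-type, time, individual, infector."""
    with open(path, "w") as fh:
        fh.write("node_type\ttime\tindividual\tinfector\n")
        for node in tree.nodes():
            infector = "" if node.infector is None else str(node.infector)
            fh.write(f"{node.kind}\t{node.time!r}\t{node.individual}\t{infector}\n")
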