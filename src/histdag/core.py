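"""Core domain types and algorithms for history sDAGs.

A *history* is a rooted, multifurcating, non-unifurcating tree in which every
node — internal and leaf — carries a label (typically a nucleotide sequence).
Histories are encoded as a special case of the *history subpartition DAG*
(history sDAG): a directed graph whose nodes are either a formal universal
ancestor (UA) or a pair ``(label, subpartition)``, where the subpartition is
the set of leaf-label sets (clades) below each child.  Because node identity
is structural, the graph union of many histories merges shared substructure,
and the union in general encodes *more* histories than were used to build it:
any subhistory below a node may be swapped for any other subhistory hanging
from an equal node.

This module provides the types, validation, conversion from labeled trees,
graph union, and enumeration / exact counting / uniform sampling of the
histories an sDAG contains.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Iterator, Sequence

from .errors import (
    DuplicateLeafError,
    EmptyCladeError,
    InvalidSDAGError,
    NotAHistoryError,
    OverlappingCladesError,
    SingletonSubpartitionError,
    UANodeError,
    UnifurcationError,
)

Label = Hashable
Clade = frozenset
Subpartition = frozenset

__all__ = [
    "Label",
    "Clade",
    "Subpartition",
    "SDAGNode",
    "UA",
    "LabeledTree",
    "History",
    "HistorySDAG",
    "Violation",
    "make_subpartition",
    "clade_union",
    "label_key",
    "clade_key",
    "node_key",
    "edge_key",
    "history_from_labeled_tree",
    "history_to_labeled_tree",
    "sdag_union",
]


# ---------------------------------------------------------------------------
# canonical ordering
# ---------------------------------------------------------------------------

def label_key(label: Label):
    """Deterministic sort key for labels (strings sort naturally)."""
    return (type(label).__name__, str(label))


def clade_key(clade: Clade):
    return tuple(sorted(label_key(l) for l in clade))


def subpartition_key(clades: Subpartition):
    return tuple(sorted(clade_key(c) for c in clades))


def node_key(v: "SDAGNode"):
    if v.is_ua:
        return (0, (), ())
    return (1, label_key(v.label), subpartition_key(v.clades))


def edge_key(edge):
    parent, child = edge
    return (node_key(parent), node_key(child))


# ---------------------------------------------------------------------------
# subpartitions and nodes
# ---------------------------------------------------------------------------

def make_subpartition(clades: Iterable[Iterable[Label]]) -> Subpartition:
    """Validate and freeze a set of clades as a subpartition.

    A subpartition is a set of pairwise-disjoint nonempty clades whose
    cardinality is not exactly one; the empty subpartition marks a leaf.
    """
    frozen = frozenset(frozenset(c) for c in clades)
    if len(frozen) == 1:
        raise SingletonSubpartitionError(
            "a subpartition may not consist of exactly one clade"
        )
    seen: set = set()
    for c in sorted(frozen, key=clade_key):
        if not c:
            raise EmptyCladeError("clades in a subpartition must be nonempty")
        if seen & c:
            raise OverlappingCladesError(
                f"clades overlap on {sorted(seen & c, key=label_key)}"
            )
        seen |= c
    return frozen


@dataclass(frozen=True, slots=True)
class SDAGNode:
    """A history sDAG node: the UA sentinel, or a (label, subpartition) pair.

    Identity is by value, so structurally equal nodes coming from
    independently built histories are merged by graph union.
    """

    label: Label
    clades: Subpartition | None  # None marks the UA node

    @property
    def is_ua(self) -> bool:
        return self.clades is None

    @property
    def is_leaf(self) -> bool:
        return self.clades is not None and not self.clades

    def clade_union(self) -> Clade:
        if self.is_ua:
            raise UANodeError("clade union is undefined for the UA node")
        if not self.clades:
            return frozenset((self.label,))
        out: frozenset = frozenset()
        for c in self.clades:
            out |= c
        return out

    def __repr__(self) -> str:  # compact, deterministic
        if self.is_ua:
            return "UA"
        if self.is_leaf:
            return f"({self.label!r})"
        clades = ",".join(
            "{" + ",".join(repr(l) for l in sorted(c, key=label_key)) + "}"
            for c in sorted(self.clades, key=clade_key)
        )
        return f"({self.label!r};{clades})"

    @staticmethod
    def make(label: Label, clades: Iterable[Iterable[Label]]) -> "SDAGNode":
        return SDAGNode(label, make_subpartition(clades))

    @staticmethod
    def leaf(label: Label) -> "SDAGNode":
        return SDAGNode(label, frozenset())


UA = SDAGNode(None, None)


def clade_union(v: SDAGNode) -> Clade:
    """The set of leaf labels below ``v``: {label} for leaves, else the union
    of its child clades."""
    return v.clade_union()


# ---------------------------------------------------------------------------
# labeled trees (input representation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledTree:
    """A rooted tree with a label on every node; the input form of a history."""

    label: Label
    children: tuple["LabeledTree", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


# ---------------------------------------------------------------------------
# the history sDAG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One validity-condition failure, naming the condition and the subject."""

    code: str
    message: str


class HistorySDAG:
    """A history sDAG: node set (containing the UA node) plus directed edges.

    Instances are immutable once constructed; all operations return new
    objects.  Equality is structural (same node and edge sets).
    """

    __slots__ = ("_edges", "_nodes", "_succ", "_pred")

    def __init__(self, edges: Iterable[tuple[SDAGNode, SDAGNode]]):
        edge_set = frozenset((p, c) for p, c in edges)
        nodes = {UA}
        succ: dict[SDAGNode, set[SDAGNode]] = {}
        pred: dict[SDAGNode, set[SDAGNode]] = {}
        for p, c in edge_set:
            nodes.add(p)
            nodes.add(c)
            succ.setdefault(p, set()).add(c)
            pred.setdefault(c, set()).add(p)
        self._edges = edge_set
        self._nodes = frozenset(nodes)
        self._succ = succ
        self._pred = pred

    # -- basic accessors ----------------------------------------------------

    @property
    def nodes(self) -> frozenset:
        return self._nodes

    @property
    def edges(self) -> frozenset:
        return self._edges

    def children(self, v: SDAGNode) -> tuple[SDAGNode, ...]:
        """Ch(v): children of ``v``, in canonical order."""
        return tuple(sorted(self._succ.get(v, ()), key=node_key))

    def children_of_clade(self, v: SDAGNode, clade: Clade) -> tuple[SDAGNode, ...]:
        """Ch(v, C): children of the node-clade pair (v, C), canonical order."""
        return tuple(
            c for c in self.children(v) if not c.is_ua and c.clade_union() == clade
        )

    def parents(self, v: SDAGNode) -> tuple[SDAGNode, ...]:
        return tuple(sorted(self._pred.get(v, ()), key=node_key))

    @property
    def ua_children(self) -> tuple[SDAGNode, ...]:
        return self.children(UA)

    def sorted_nodes(self) -> list[SDAGNode]:
        return sorted(self._nodes, key=node_key)

    def sorted_edges(self) -> list[tuple[SDAGNode, SDAGNode]]:
        return sorted(self._edges, key=edge_key)

    def leaf_nodes(self) -> list[SDAGNode]:
        return [v for v in self.sorted_nodes() if v.is_leaf]

    # -- equality -----------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, HistorySDAG):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self._nodes, self._edges))

    def __repr__(self) -> str:
        return (
            f"{type(self).__name__}(nodes={len(self._nodes)}, "
            f"edges={len(self._edges)})"
        )

    # -- structural queries -------------------------------------------------

    def topological_order(self) -> list[SDAGNode]:
        """Nodes in a deterministic topological order, UA first.

        Raises :class:`InvalidSDAGError` if the graph contains a cycle.
        """
        indeg = {v: 0 for v in self._nodes}
        for _, c in self._edges:
            indeg[c] += 1
        ready = sorted((v for v, d in indeg.items() if d == 0), key=node_key)
        order: list[SDAGNode] = []
        while ready:
            v = ready.pop(0)
            order.append(v)
            inserted = []
            for c in self.children(v):
                indeg[c] -= 1
                if indeg[c] == 0:
                    inserted.append(c)
            if inserted:
                ready = sorted(ready + inserted, key=node_key)
        if len(order) != len(self._nodes):
            raise InvalidSDAGError("graph contains a cycle")
        return order

    def reachable_from(self, start: SDAGNode) -> set[SDAGNode]:
        seen = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for c in self._succ.get(v, ()):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return seen

    def validate(self) -> list[Violation]:
        """Check every defining condition of the history sDAG; return all
        violations (empty list means valid)."""
        out: list[Violation] = []
        if not self._succ.get(UA):
            out.append(Violation("EMPTY", "UA node has no descendant edges"))
        if self._pred.get(UA):
            out.append(Violation("UA_INCOMING", "UA node accepts no incoming edges"))
        for p, c in self.sorted_edges():
            if c.is_ua:
                out.append(Violation("BAD_EDGE", f"edge into UA from {p!r}"))
                continue
            if not p.is_ua and c.clade_union() not in p.clades:
                out.append(
                    Violation(
                        "BAD_EDGE",
                        f"clade union of {c!r} is not a child clade of {p!r}",
                    )
                )
        for v in self.sorted_nodes():
            if v.is_ua or v.is_leaf:
                continue
            for clade in sorted(v.clades, key=clade_key):
                if not self.children_of_clade(v, clade):
                    out.append(
                        Violation(
                            "MISSING_CLADE_EDGE",
                            f"no edge descends from node-clade pair "
                            f"({v!r}, {set(sorted(clade, key=label_key))})",
                        )
                    )
        reachable = self.reachable_from(UA)
        for v in self.sorted_nodes():
            if v not in reachable:
                out.append(Violation("UNREACHABLE", f"{v!r} unreachable from UA"))
        try:
            self.topological_order()
        except InvalidSDAGError:
            out.append(Violation("CYCLE", "graph contains a cycle"))
        return out

    def is_history(self) -> bool:
        """True iff the UA node has one child and every node-clade pair has
        exactly one descendant edge."""
        if len(self._succ.get(UA, ())) != 1:
            return False
        for v in self._nodes:
            if v.is_ua or v.is_leaf:
                continue
            for clade in v.clades:
                if len(self.children_of_clade(v, clade)) != 1:
                    return False
        return True

    def contains_history(self, t: "History") -> bool:
        """True iff ``t`` is a trim of this sDAG (node and edge subsets)."""
        return t.nodes <= self._nodes and t.edges <= self._edges

    # -- counting, enumeration, sampling ------------------------------------

    def _subhistory_counts(self) -> dict[SDAGNode, int]:
        """N(v): the exact number of subhistories rooted at each node."""
        counts: dict[SDAGNode, int] = {}
        for v in reversed(self.topological_order()):
            if v.is_ua:
                continue
            if v.is_leaf:
                counts[v] = 1
                continue
            total = 1
            for clade in v.clades:
                total *= sum(counts[c] for c in self.children_of_clade(v, clade))
            counts[v] = total
        return counts

    def count_histories(self) -> int:
        """The exact number of distinct histories this sDAG expresses."""
        counts = self._subhistory_counts()
        return sum(counts[c] for c in self.ua_children)

    def _subhistory_edge_sets(self, v: SDAGNode) -> Iterator[tuple]:
        """Lazily yield the edge sets of all subhistories rooted at ``v``."""
        clades = sorted(v.clades, key=clade_key)

        def rec(i: int) -> Iterator[tuple]:
            if i == len(clades):
                yield ()
                return
            for child in self.children_of_clade(v, clades[i]):
                for sub in self._subhistory_edge_sets(child):
                    for rest in rec(i + 1):
                        yield ((v, child),) + sub + rest

        yield from rec(0)

    def iter_histories(self) -> Iterator["History"]:
        """Lazily yield each distinct history in this sDAG exactly once."""
        for ua_child in self.ua_children:
            for edges in self._subhistory_edge_sets(ua_child):
                yield History(((UA, ua_child),) + edges)

    def sample_history(self, seed: int | random.Random) -> "History":
        """Draw one history uniformly at random from those in this sDAG.

        Each edge choice is made with probability proportional to the number
        of subhistories below its target, which makes the draw exactly
        uniform over histories.  Deterministic given the seed.
        """
        rng = seed if isinstance(seed, random.Random) else random.Random(seed)
        counts = self._subhistory_counts()

        def weighted_choice(options: Sequence[SDAGNode]) -> SDAGNode:
            weights = [counts[o] for o in options]
            total = sum(weights)
            r = rng.randrange(total)
            acc = 0
            for o, w in zip(options, weights):
                acc += w
                if r < acc:
                    return o
            raise AssertionError("unreachable")

        root = weighted_choice(self.ua_children)
        edges = [(UA, root)]
        stack = [root]
        while stack:
            v = stack.pop()
            if v.is_leaf:
                continue
            for clade in sorted(v.clades, key=clade_key):
                child = weighted_choice(self.children_of_clade(v, clade))
                edges.append((v, child))
                stack.append(child)
        return History(edges)


class History(HistorySDAG):
    """A history: an sDAG with a unique UA child and exactly one descendant
    edge per node-clade pair — equivalently, an internally labeled tree."""

    __slots__ = ()

    def __init__(self, edges: Iterable[tuple[SDAGNode, SDAGNode]]):
        super().__init__(edges)
        if not self.is_history():
            raise NotAHistoryError(
                "structure has a node-clade pair without a unique descendant "
                "edge, or the UA node lacks a unique child"
            )

    @property
    def root(self) -> SDAGNode:
        return self.ua_children[0]

    def leaf_labels(self) -> Clade:
        return self.root.clade_union()


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _contract_unifurcations(tree: LabeledTree) -> LabeledTree:
    # drop each unifurcating chain, keeping the bottom node of the chain
    while len(tree.children) == 1:
        tree = tree.children[0]
    return LabeledTree(tree.label, tuple(_contract_unifurcations(c) for c in tree.children))


def history_from_labeled_tree(
    tree: LabeledTree,
    fixed_root_as_leaf: bool = False,
    contract_unifurcations: bool = False,
) -> History:
    """Convert a fully labeled rooted tree into the equivalent history.

    Each node becomes a ``(label, set of child clades)`` pair and a UA node is
    attached above the root.  With ``fixed_root_as_leaf``, the root's label is
    additionally attached as a leaf-node child of the root, accommodating
    data sets with a fixed ancestral sequence (which may otherwise force a
    unifurcation at the root).  Unifurcating chains are an error unless
    ``contract_unifurcations`` is set, in which case each chain is replaced by
    its bottom node (silently discarding the labels above it).
    """
    if contract_unifurcations:
        tree = _contract_unifurcations(tree)
    if fixed_root_as_leaf:
        tree = LabeledTree(
            tree.label, tree.children + (LabeledTree(tree.label),)
        )

    edges: list[tuple[SDAGNode, SDAGNode]] = []
    seen_leaves: set = set()

    def build(node: LabeledTree) -> SDAGNode:
        if node.is_leaf:
            if node.label in seen_leaves:
                raise DuplicateLeafError(
                    f"two leaves share the label {node.label!r}"
                )
            seen_leaves.add(node.label)
            return SDAGNode.leaf(node.label)
        if len(node.children) == 1:
            raise UnifurcationError(
                f"node labeled {node.label!r} has exactly one child"
            )
        child_nodes = [build(c) for c in node.children]
        sub = make_subpartition(c.clade_union() for c in child_nodes)
        if len(sub) != len(child_nodes):
            # two children produced the same clade — only possible through
            # duplicate leaf labels deeper in the tree
            raise DuplicateLeafError("children have non-distinct clades")
        v = SDAGNode(node.label, sub)
        edges.extend((v, c) for c in child_nodes)
        return v

    root = build(tree)
    edges.append((UA, root))
    return History(edges)


def history_to_labeled_tree(t: History) -> LabeledTree:
    """Inverse of :func:`history_from_labeled_tree` (without the UA node)."""

    def build(v: SDAGNode) -> LabeledTree:
        if v.is_leaf:
            return LabeledTree(v.label)
        children = []
        for clade in sorted(v.clades, key=clade_key):
            (child,) = t.children_of_clade(v, clade)
            children.append(build(child))
        return LabeledTree(v.label, tuple(children))

    return build(t.root)


def sdag_union(inputs: Sequence[HistorySDAG]) -> HistorySDAG:
    """The graph union of history sDAGs: union of node sets and edge sets.

    Because node identity is structural, shared substructure merges, and the
    union in general expresses histories beyond the inputs (all combinations
    of subhistory swaps below equal nodes).
    """
    if not inputs:
        raise ValueError("sdag_union requires at least one input sDAG")
    edges: set = set()
    for d in inputs:
        edges |= d.edges
    return HistorySDAG(edges)
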