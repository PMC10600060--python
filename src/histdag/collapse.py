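"""Collapsing edges whose endpoints satisfy a predicate.

Edges joining two non-leaf nodes that carry the same label add no mutation
information: collapsing them introduces multifurcations without changing a
history's parsimony score, and every history determines a unique fully
collapsed form regardless of the order in which edges are collapsed.

Collapsing inside a whole sDAG is subtler than collapsing one history: an
edge descending from a node-clade pair may need collapsing while its sibling
edges do not, so the procedure must occasionally *add* nodes (the merged
parent).  The queue-driven algorithm here processes edges from the UA node
downward, merging each collapsible edge's endpoints into a new parent node,
rewiring grandparents, siblings and grandchildren onto it, and pruning nodes
left without required edges.  The result expresses exactly the per-history
collapses of every history in the input.
"""

from __future__ import annotations

import random
from collections import deque
from typing import Callable, Iterable

from .core import (
    HistorySDAG,
    History,
    SDAGNode,
    UA,
    edge_key,
    node_key,
)
from .errors import (
    LeafTargetError,
    NotAnEdgeError,
    UAParentError,
)

__all__ = [
    "label_predicate",
    "collapse_edge_in_history",
    "collapse_history",
    "collapse_sdag",
]

CollapsePredicate = Callable[[SDAGNode, SDAGNode], bool]


def label_predicate(parent: SDAGNode, child: SDAGNode) -> bool:
    """The standard predicate: collapse edges joining equal labels."""
    return (not parent.is_ua) and parent.label == child.label


def _collapsible(parent: SDAGNode, child: SDAGNode, b: CollapsePredicate) -> bool:
    # edges into leaves are never collapsible (sampled ancestors stay),
    # and UA edges are never collapsible (the UA node has no label)
    return (not parent.is_ua) and (not child.is_leaf) and b(parent, child)


def _merged_parent(parent: SDAGNode, child: SDAGNode) -> SDAGNode:
    """The node replacing both endpoints: the child clade CU(child) of the
    parent is replaced by the child's own child clades."""
    clade = child.clade_union()
    return SDAGNode(parent.label, (parent.clades - {clade}) | child.clades)


# ---------------------------------------------------------------------------
# single histories
# ---------------------------------------------------------------------------

def collapse_edge_in_history(
    t: History, parent: SDAGNode, child: SDAGNode
) -> History:
    """Collapse one edge of a history, merging its endpoints.

    Both endpoints map to ``(parent.label, parent.clades with CU(child)
    replaced by child.clades)``; every other node is fixed; edges are
    re-mapped through this node map with the collapsed edge removed.  The
    result is a valid history with exactly one edge fewer.
    """
    if (parent, child) not in t.edges:
        raise NotAnEdgeError(f"({parent!r}, {child!r}) is not an edge of the history")
    if parent.is_ua:
        raise UAParentError("edges descending from the UA node cannot be collapsed")
    if child.is_leaf:
        raise LeafTargetError("edges targeting a leaf node cannot be collapsed")
    merged = _merged_parent(parent, child)

    def q(v: SDAGNode) -> SDAGNode:
        return merged if v in (parent, child) else v

    return History(
        (q(a), q(b)) for a, b in t.edges if (a, b) != (parent, child)
    )


def collapse_history(
    t: History, b: CollapsePredicate = label_predicate
) -> History:
    """Repeatedly collapse collapsible edges of a history until none remain.

    The collapsed form is unique — the order of edge collapses has no effect
    — so this routine simply processes edges in canonical order.
    """
    while True:
        for p, c in t.sorted_edges():
            if _collapsible(p, c, b):
                t = collapse_edge_in_history(t, p, c)
                break
        else:
            return t


# ---------------------------------------------------------------------------
# whole sDAGs
# ---------------------------------------------------------------------------

class _MutableDag:
    """Adjacency-indexed mutable graph used only inside collapse_sdag."""

    def __init__(self, d: HistorySDAG):
        self.edges: set = set(d.edges)
        self.succ: dict[SDAGNode, set] = {}
        self.pred: dict[SDAGNode, set] = {}
        self.nodes: set = set(d.nodes)
        for p, c in self.edges:
            self.succ.setdefault(p, set()).add(c)
            self.pred.setdefault(c, set()).add(p)

    def add_edge(self, p: SDAGNode, c: SDAGNode) -> None:
        self.nodes.add(p)
        self.nodes.add(c)
        self.edges.add((p, c))
        self.succ.setdefault(p, set()).add(c)
        self.pred.setdefault(c, set()).add(p)

    def remove_edge(self, p: SDAGNode, c: SDAGNode) -> None:
        self.edges.discard((p, c))
        self.succ.get(p, set()).discard(c)
        self.pred.get(c, set()).discard(p)

    def remove_node(self, v: SDAGNode) -> None:
        """Remove a node, cascading to children left without any parent."""
        if v not in self.nodes:
            return
        self.nodes.discard(v)
        for c in sorted(self.succ.get(v, set()), key=node_key):
            self.remove_edge(v, c)
            if not self.pred.get(c):
                self.remove_node(c)
        for p in sorted(self.pred.get(v, set()), key=node_key):
            self.remove_edge(p, v)


def _initial_queue(
    d: HistorySDAG, rng: random.Random | None
) -> deque:
    """Edges ordered so parents precede the edges below them (UA-first).

    With an rng, a random linear extension of that partial order is drawn, so
    order-invariance of the whole procedure can be exercised directly.
    """
    depth: dict[SDAGNode, int] = {UA: 0}
    for v in d.topological_order():
        for c in d.children(v):
            prev = depth.get(c)
            nd = depth[v] + 1
            depth[c] = nd if prev is None else max(prev, nd)
    edges = sorted(d.edges, key=lambda e: (depth[e[0]], edge_key(e)))
    if rng is not None:
        # random linear extension: repeatedly emit a random edge all of whose
        # "parent" edges (those ending at its source) are already emitted
        remaining = list(edges)
        out = []
        while remaining:
            pending_targets = {c for _, c in remaining}
            ready = [e for e in remaining if e[0] is UA or e[0] not in pending_targets]
            pick = rng.choice(ready)
            out.append(pick)
            remaining.remove(pick)
        edges = out
    return deque(edges)


def collapse_sdag(
    d: HistorySDAG,
    b: CollapsePredicate = label_predicate,
    rng: random.Random | None = None,
) -> HistorySDAG:
    """Collapse every collapsible edge of a history sDAG.

    Processes a queue of edges seeded in UA-first order.  For each
    collapsible edge (v_p, v_c) still present in the graph:

    * the new parent ``v_p' = (label_p, clades_p with CU(v_c) replaced by
      v_c's clades)`` is added (merging with an existing equal node);
    * every parent of v_p gains an edge to v_p'; every child of v_p over a
      clade other than CU(v_c) and every child of v_c becomes a child of
      v_p' (all new edges are enqueued);
    * the collapsed edge is removed; v_p is removed if its node-clade pair
      over CU(v_c) is now empty; v_c is removed if orphaned; removals
      cascade to unreachable descendants.

    The histories of the result are exactly the per-history collapses of the
    input's histories, and the queue order (any order in which parents
    precede the edges below them, randomized via ``rng``) has no effect on
    the outcome.
    """
    g = _MutableDag(d)
    queue = _initial_queue(d, rng)
    while queue:
        vp, vc = queue.popleft()
        if (vp, vc) not in g.edges:
            continue  # stale entry: removed by an earlier iteration
        if not _collapsible(vp, vc, b):
            continue
        clade = vc.clade_union()
        merged = _merged_parent(vp, vc)
        for v in sorted(g.pred.get(vp, set()), key=node_key):
            g.add_edge(v, merged)
            queue.appendleft((v, merged))
        for v in sorted(g.succ.get(vp, set()), key=node_key):
            if v.clade_union() != clade:
                g.add_edge(merged, v)
                queue.appendleft((merged, v))
        for v in sorted(g.succ.get(vc, set()), key=node_key):
            g.add_edge(merged, v)
            queue.appendleft((merged, v))
        g.remove_edge(vp, vc)
        if not any(
            v.clade_union() == clade for v in g.succ.get(vp, set())
        ):
            g.remove_node(vp)
        if vc in g.nodes and not g.pred.get(vc):
            g.remove_node(vc)
    return HistorySDAG(g.edges)
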