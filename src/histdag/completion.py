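"""Completion: adding every edge compatible with clade unions.

An sDAG edge must target a node whose clade union is a child clade of its
parent.  *Completion* adds every edge that this rule permits among the
existing nodes — no new nodes — so the completed sDAG allows any subhistories
on the same leaf labels to swap, regardless of their parent nodes.  The new
histories carry no weight guarantee, but trimming the completed sDAG can
discover minimum-weight histories absent from the original.

This module also builds the *complete* sDAG on a tiny label set — the graph
union of every possible history — which is astronomically large in general
and is provided purely as an enumeration oracle.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable

from .core import (
    Clade,
    HistorySDAG,
    SDAGNode,
    UA,
    clade_key,
    label_key,
    make_subpartition,
)
from .errors import SizeGuardError

__all__ = ["complete", "complete_sdag_on_labels", "set_partitions"]


def complete(d: HistorySDAG) -> HistorySDAG:
    """Add every clade-union-compatible edge among the existing nodes.

    An edge (v, v') is added whenever CU(v') is a child clade of v.  The UA
    node gains an edge to every node whose clade union matches the clade
    union of an existing UA child, so the set of permissible root clades is
    unchanged.  Node set, and hence leaf-label sets, are unchanged; the
    result's histories are a superset of the input's.
    """
    by_cu: dict[Clade, list[SDAGNode]] = {}
    for v in d.sorted_nodes():
        if v.is_ua:
            continue
        by_cu.setdefault(v.clade_union(), []).append(v)

    edges: set = set()
    for v in d.nodes:
        if v.is_ua or v.is_leaf:
            continue
        for clade in v.clades:
            for target in by_cu[clade]:
                edges.add((v, target))
    root_clades = {c.clade_union() for c in d.ua_children}
    for clade in root_clades:
        for target in by_cu[clade]:
            edges.add((UA, target))
    return HistorySDAG(edges)


def set_partitions(items: list, min_blocks: int = 1) -> Iterable[list[list]]:
    """All partitions of ``items`` into at least ``min_blocks`` blocks."""
    if not items:
        if min_blocks <= 0:
            yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest, 0):
        # put first into an existing block
        if len(smaller) >= min_blocks:
            for i in range(len(smaller)):
                yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
        # or into a block of its own
        if len(smaller) + 1 >= min_blocks:
            yield [[first]] + smaller


def complete_sdag_on_labels(
    labels: Iterable,
    leaf_labels: Iterable,
    max_leaves: int = 5,
    max_labels: int = 6,
) -> HistorySDAG:
    """The graph union of *all* histories on ``leaf_labels`` with internal
    labels drawn from ``labels``.

    Size-guarded: the object is super-exponential in the number of leaves and
    is intended only as a brute-force containment oracle in tests.  Nodes are
    every leaf plus every ``(label, partition-of-a-subset)`` pair; every
    compatible edge is present; UA edges point at every node whose clade
    union is the full leaf set.
    """
    labels = sorted(set(labels), key=label_key)
    leaves = sorted(set(leaf_labels), key=label_key)
    if len(leaves) > max_leaves or len(labels) > max_labels:
        raise SizeGuardError(
            f"complete sDAG guard: {len(leaves)} leaves / {len(labels)} labels "
            f"exceeds ({max_leaves}, {max_labels})"
        )
    if not leaves:
        raise ValueError("at least one leaf label required")

    leaf_nodes = {l: SDAGNode.leaf(l) for l in leaves}
    full = frozenset(leaves)

    if len(leaves) == 1:
        return HistorySDAG([(UA, leaf_nodes[leaves[0]])])

    # every internal node: a label and a partition (>=2 blocks) of a subset
    by_cu: dict[Clade, list[SDAGNode]] = {frozenset((l,)): [leaf_nodes[l]] for l in leaves}
    subsets = [
        frozenset(s)
        for mask in range(1, 2 ** len(leaves))
        if bin(mask).count("1") >= 2
        for s in [[l for i, l in enumerate(leaves) if mask >> i & 1]]
    ]
    for subset in subsets:
        for blocks in set_partitions(sorted(subset, key=label_key), min_blocks=2):
            sub = make_subpartition(blocks)
            for label in labels:
                by_cu.setdefault(subset, []).append(SDAGNode(label, sub))

    edges: set = set()
    for nodes in by_cu.values():
        for v in nodes:
            if v.is_leaf:
                continue
            for clade in v.clades:
                for target in by_cu[clade]:
                    edges.add((v, target))
    for target in by_cu[full]:
        if not target.is_leaf:
            edges.add((UA, target))
    return HistorySDAG(edges)
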