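"""History weights: Hamming parsimony, the minimum-weight dynamic program,
the minimum-weight trim, and exact weight distributions.

A history's weight is the sum of an edge weight function f over its edges.
For parsimony, f is Hamming distance between the endpoint sequence labels, so
a history's weight is its parsimony score.  The decomposition over edges is
only valid because internal nodes carry complete, unambiguous sequences: f
must report an edge's contribution independent of surrounding structure.

The per-node minimum M_f(v) — the least weight of any subhistory rooted at
v — satisfies a recursion over node-clade pairs:

    M_f(leaf)  = 0 (the additive identity)
    M_f(v, C)  = min over children v_c of (v, C) of  M_f(v_c) + f(v, v_c)
    M_f(v)     = sum over child clades C of  M_f(v, C)

provided the weight set is *clade-ordered*: its total order respects addition
on the relevant weight subsets.  One postorder pass fills the table; keeping
exactly the edges that achieve the per-pair minima (and discarding what
becomes unreachable) yields an sDAG whose histories are exactly the
minimum-weight histories of the original.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Hashable

from .core import (
    Clade,
    HistorySDAG,
    History,
    SDAGNode,
    UA,
    clade_key,
    node_key,
)
from .errors import (
    AmbiguousCharacterError,
    LengthMismatchError,
    SizeGuardError,
)

__all__ = [
    "WeightContract",
    "EdgeWeightFunction",
    "MinWeightTable",
    "INTEGER_CONTRACT",
    "hamming_distance",
    "hamming_parsimony",
    "history_weight",
    "min_weight_table",
    "min_weight_trim",
    "weight_distribution",
]


@dataclass(frozen=True)
class WeightContract:
    """An addition with identity plus a total order on the weight set.

    The order must be *clade-ordered* for the sDAG and edge weight function
    it is used with: ``a < b  iff  a + c < b + c`` on the weight subsets the
    dynamic program compares.  Nonnegative integers under ordinary addition
    and order (the default) are clade-ordered for any context-free
    nonnegative f; for other contracts this is the caller's obligation and is
    only spot-checked.
    """

    add: Callable
    identity: Hashable
    less_than: Callable

    def equal(self, a, b) -> bool:
        return not self.less_than(a, b) and not self.less_than(b, a)

    def minimum(self, items):
        items = list(items)
        if not items:
            raise ValueError("minimum of empty collection")
        best = items[0]
        for x in items[1:]:
            if self.less_than(x, best):
                best = x
        return best


INTEGER_CONTRACT = WeightContract(
    add=lambda a, b: a + b, identity=0, less_than=lambda a, b: a < b
)


@dataclass(frozen=True)
class EdgeWeightFunction:
    """An edge weight function together with its weight contract.

    ``fn(parent, child)`` must be a pure function of the two endpoint nodes
    (label and subpartition), never of surrounding structure.
    """

    fn: Callable[[SDAGNode, SDAGNode], Hashable]
    contract: WeightContract = INTEGER_CONTRACT

    def __call__(self, parent: SDAGNode, child: SDAGNode):
        return self.fn(parent, child)


# ---------------------------------------------------------------------------
# Hamming parsimony
# ---------------------------------------------------------------------------

UNAMBIGUOUS_NUCLEOTIDES = frozenset("ACGT")


def _check_sequence(seq, alphabet: frozenset) -> str:
    s = str(seq)
    bad = set(s) - set(alphabet)
    if bad:
        raise AmbiguousCharacterError(
            f"sequence contains characters outside the unambiguous alphabet: "
            f"{sorted(bad)}"
        )
    return s


def hamming_distance(a, b, alphabet: frozenset = UNAMBIGUOUS_NUCLEOTIDES) -> int:
    """Number of positions at which two equal-length sequences differ."""
    sa = _check_sequence(a, alphabet)
    sb = _check_sequence(b, alphabet)
    if len(sa) != len(sb):
        raise LengthMismatchError(
            f"sequence lengths differ: {len(sa)} vs {len(sb)}"
        )
    return sum(x != y for x, y in zip(sa, sb))


def hamming_parsimony(
    ua_reference=None,
    alphabet: str | frozenset = UNAMBIGUOUS_NUCLEOTIDES,
) -> EdgeWeightFunction:
    """The parsimony edge weight: Hamming distance between endpoint labels.

    The UA node carries no label, so edges out of it get weight 0 by default,
    which makes a history's weight equal the standard parsimony score of the
    corresponding tree.  Passing ``ua_reference`` instead scores each UA edge
    as the distance from that reference sequence to the root label,
    supporting fixed-ancestor analyses.
    """
    alpha = frozenset(alphabet)

    def fn(parent: SDAGNode, child: SDAGNode) -> int:
        if parent.is_ua:
            if ua_reference is None:
                return 0
            return hamming_distance(ua_reference, child.label, alpha)
        return hamming_distance(parent.label, child.label, alpha)

    return EdgeWeightFunction(fn=fn, contract=INTEGER_CONTRACT)


# ---------------------------------------------------------------------------
# weights of histories
# ---------------------------------------------------------------------------

def history_weight(t: History, f: EdgeWeightFunction):
    """g_f(t): the sum of f over the edges of a history (the parsimony score
    when f is Hamming distance)."""
    total = f.contract.identity
    for p, c in t.sorted_edges():
        total = f.contract.add(total, f(p, c))
    return total


# ---------------------------------------------------------------------------
# the minimum-weight dynamic program
# ---------------------------------------------------------------------------

@dataclass
class MinWeightTable:
    """M_f values for every node and node-clade pair, plus M_f at the UA node
    (the minimum weight over all histories in the sDAG)."""

    node_min: dict = field(default_factory=dict)
    pair_min: dict = field(default_factory=dict)
    ua_min: Hashable = None


def min_weight_table(d: HistorySDAG, f: EdgeWeightFunction) -> MinWeightTable:
    """Fill the M_f table in one postorder pass over the sDAG."""
    contract = f.contract
    table = MinWeightTable()
    for v in reversed(d.topological_order()):
        if v.is_ua:
            continue
        if v.is_leaf:
            table.node_min[v] = contract.identity
            continue
        total = contract.identity
        for clade in sorted(v.clades, key=clade_key):
            best = contract.minimum(
                contract.add(table.node_min[c], f(v, c))
                for c in d.children_of_clade(v, clade)
            )
            table.pair_min[(v, clade)] = best
            total = contract.add(total, best)
        table.node_min[v] = total
    table.ua_min = contract.minimum(
        contract.add(table.node_min[c], f(UA, c)) for c in d.ua_children
    )
    return table


def min_weight_trim(d: HistorySDAG, f: EdgeWeightFunction) -> HistorySDAG:
    """Trim ``d`` to the sDAG expressing exactly its minimum-weight histories.

    Keeps each edge (v, v_c) iff it achieves the per-pair minimum
    M_f(v, CU(v_c)); UA edges are kept iff they achieve M_f at the UA node.
    Nodes unreachable through kept edges are dropped, then kept edges
    touching dropped nodes are dropped.  All ties are retained.
    """
    contract = f.contract
    table = min_weight_table(d, f)
    kept: set = set()
    for p, c in d.edges:
        w = contract.add(table.node_min[c], f(p, c))
        if p.is_ua:
            if contract.equal(w, table.ua_min):
                kept.add((p, c))
        elif contract.equal(w, table.pair_min[(p, c.clade_union())]):
            kept.add((p, c))
    partial = HistorySDAG(kept)
    reachable = partial.reachable_from(UA)
    return HistorySDAG(
        (p, c) for p, c in kept if p in reachable and c in reachable
    )


def weight_distribution(
    d: HistorySDAG,
    f: EdgeWeightFunction,
    max_distinct_weights: int = 10_000,
) -> dict:
    """Exact counts of histories in ``d`` at each weight.

    Computed by a postorder convolution: each node's per-clade weight-count
    maps (children shifted by the edge weight, then summed over children) are
    convolved across clades.  The total mass equals ``count_histories(d)``.
    A guard aborts if the number of distinct weights exceeds
    ``max_distinct_weights`` (convolution can blow up on pathological weight
    functions).
    """
    contract = f.contract
    dists: dict[SDAGNode, Counter] = {}

    def guard(counter: Counter) -> Counter:
        if len(counter) > max_distinct_weights:
            raise SizeGuardError(
                f"weight distribution exceeds {max_distinct_weights} distinct "
                f"weights"
            )
        return counter

    for v in reversed(d.topological_order()):
        if v.is_ua:
            continue
        if v.is_leaf:
            dists[v] = Counter({contract.identity: 1})
            continue
        acc = Counter({contract.identity: 1})
        for clade in sorted(v.clades, key=clade_key):
            clade_dist: Counter = Counter()
            for c in d.children_of_clade(v, clade):
                shift = f(v, c)
                for w, n in dists[c].items():
                    clade_dist[contract.add(w, shift)] += n
            merged: Counter = Counter()
            for w1, n1 in acc.items():
                for w2, n2 in clade_dist.items():
                    merged[contract.add(w1, w2)] += n1 * n2
            acc = guard(merged)
        dists[v] = acc
    total: Counter = Counter()
    for c in d.ua_children:
        shift = f(UA, c)
        for w, n in dists[c].items():
            total[contract.add(w, shift)] += n
    return dict(guard(total))
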