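"""Synthetic data: random histories, random sequence evolution on them, and
brute-force maximum-parsimony history sets on small inputs.

These generators are first-class package code: they define the study
conditions under which the sDAG machinery is exercised and cross-checked.
The brute-force search enumerates every rooted multifurcating non-unifurcating
topology (via set partitions of the leaf set, mirroring the subpartition
structure directly) and every internal label assignment with per-site states
restricted to the characters observed at that site among the leaves — a
standard parsimony fact sufficient for optimality, additionally sanity-checked
against an independent per-site Sankoff dynamic program.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

from .collapse import collapse_history
from .completion import set_partitions
from .core import (
    HistorySDAG,
    History,
    LabeledTree,
    SDAGNode,
    UA,
    history_from_labeled_tree,
    label_key,
)
from .errors import DuplicateLeafError, SizeGuardError

__all__ = [
    "SimulationConfig",
    "random_history",
    "random_history_on_leaves",
    "random_sdag",
    "bruteforce_mp_histories",
    "small_parsimony_score",
    "enumerate_histories_oracle",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the random-history generator.

    Defaults give small, densely related sequence sets: 5 leaves evolving
    length-8 sequences at 0.1 substitutions per site per edge, so roughly
    40% of edges carry no mutation at all (exercising label-collapsing) while
    leaf sets still span several distinct parsimony optima.
    """

    n_leaves: int = 5
    sequence_length: int = 8
    alphabet: str = "ACGT"
    mutation_rate_per_site: float = 0.1
    multifurcation_probability: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        for p in (self.mutation_rate_per_site, self.multifurcation_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


class _TreeNode:
    __slots__ = ("children", "label")

    def __init__(self, children=()):
        self.children = list(children)
        self.label = None

    def freeze(self) -> LabeledTree:
        return LabeledTree(self.label, tuple(c.freeze() for c in self.children))


def _random_topology(n_leaves: int, multi_p: float, rng: random.Random) -> _TreeNode:
    """Merge lineages until one remains; extra lineages join a merge with
    probability ``multi_p`` each, producing multifurcations."""
    lineages = [_TreeNode() for _ in range(n_leaves)]
    while len(lineages) > 1:
        k = 2
        while k < len(lineages) and rng.random() < multi_p:
            k += 1
        picked = rng.sample(range(len(lineages)), k)
        merged = _TreeNode([lineages[i] for i in picked])
        lineages = [l for i, l in enumerate(lineages) if i not in picked]
        lineages.append(merged)
    return lineages[0]


def _mutate(seq: str, rate: float, alphabet: str, rng: random.Random) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([c for c in alphabet if c != ch]))
        else:
            out.append(ch)
    return "".join(out)


def _distinct_leaves(root: _TreeNode, alphabet: str) -> None:
    """Deterministically perturb duplicate leaf sequences until all differ."""
    seen: set[str] = set()

    def visit(node: _TreeNode) -> None:
        if not node.children:
            seq, pos = node.label, 0
            while seq in seen:
                i = pos % len(seq)
                ch = seq[i]
                nxt = alphabet[(alphabet.index(ch) + 1) % len(alphabet)]
                seq = seq[:i] + nxt + seq[i + 1 :]
                pos += 1
            node.label = seq
            seen.add(seq)
        for c in node.children:
            visit(c)

    visit(root)


def random_history(cfg: SimulationConfig) -> History:
    """A random rooted multifurcating history with sequence labels evolved
    down the tree; leaf labels are perturbed minimally if needed so they are
    pairwise distinct.  Deterministic given ``cfg.seed``."""
    rng = random.Random(cfg.seed)
    if cfg.n_leaves == 1:
        seq = "".join(rng.choice(cfg.alphabet) for _ in range(cfg.sequence_length))
        return history_from_labeled_tree(LabeledTree(seq))
    root = _random_topology(cfg.n_leaves, cfg.multifurcation_probability, rng)
    root.label = "".join(
        rng.choice(cfg.alphabet) for _ in range(cfg.sequence_length)
    )

    def evolve(node: _TreeNode) -> None:
        for c in node.children:
            c.label = _mutate(node.label, cfg.mutation_rate_per_site, cfg.alphabet, rng)
            evolve(c)

    evolve(root)
    _distinct_leaves(root, cfg.alphabet)
    return history_from_labeled_tree(root.freeze())


def random_history_on_leaves(
    leaf_labels: Iterable[str],
    rng: random.Random,
    multifurcation_probability: float = 0.25,
) -> History:
    """A random history over a *fixed* set of leaf sequence labels.

    Topology is random; each internal node's sequence is drawn site-by-site
    from the characters observed at that site among its descendant leaves.
    Useful for building sDAGs whose histories share one leaf set but span a
    range of parsimony scores.
    """
    leaves = sorted(set(leaf_labels), key=label_key)
    root = _random_topology(len(leaves), multifurcation_probability, rng)
    order = list(range(len(leaves)))
    rng.shuffle(order)
    it = iter(order)

    def assign(node: _TreeNode) -> str:
        if not node.children:
            node.label = leaves[next(it)]
            return node.label
        below = [assign(c) for c in node.children]
        node.label = "".join(
            rng.choice(sorted({seq[i] for seq in below}))
            for i in range(len(below[0]))
        )
        return node.label

    assign(root)
    return history_from_labeled_tree(root.freeze())


def random_sdag(
    cfg: SimulationConfig, n_histories: int = 3
) -> HistorySDAG:
    """Union of one evolved random history and ``n_histories - 1`` further
    random histories on the same leaf set.  Deterministic given ``cfg.seed``."""
    from .core import sdag_union

    first = random_history(cfg)
    rng = random.Random(cfg.seed + 1)
    leaves = sorted(first.leaf_labels(), key=label_key)
    extras = [
        random_history_on_leaves(leaves, rng, cfg.multifurcation_probability)
        for _ in range(n_histories - 1)
    ]
    return sdag_union([first] + extras)


# ---------------------------------------------------------------------------
# brute-force maximum parsimony
# ---------------------------------------------------------------------------

def _topologies(leaves: Sequence[str]) -> Iterable[LabeledTree]:
    """Every rooted multifurcating non-unifurcating shape on the given
    leaves, with internal labels left as ``None`` placeholders."""
    if len(leaves) == 1:
        yield LabeledTree(leaves[0])
        return
    for blocks in set_partitions(sorted(leaves, key=label_key), min_blocks=2):
        for combo in product(*(_topologies(b) for b in blocks)):
            yield LabeledTree(None, tuple(combo))


def _internal_nodes(tree: LabeledTree, acc: list) -> list:
    if not tree.is_leaf:
        acc.append(tree)
        for c in tree.children:
            _internal_nodes(c, acc)
    return acc


def _site_cost(tree: LabeledTree, assignment: Mapping[int, str], site: int) -> int:
    """Mutations at one site, given per-internal-node character choices."""
    cost = 0
    stack = [tree]
    while stack:
        node = stack.pop()
        pc = assignment[id(node)] if not node.is_leaf else node.label[site]
        for c in node.children:
            cc = assignment[id(c)] if not c.is_leaf else c.label[site]
            cost += pc != cc
            stack.append(c)
    return cost


def small_parsimony_score(tree: LabeledTree, site_states: Iterable[str] = "ACGT") -> int:
    """Sankoff unit-cost small-parsimony score of a leaf-labeled shape
    (internal labels ignored), summed over sites.  Independent of the
    brute-force enumeration; used as a cross-check."""
    leaves: list[LabeledTree] = []

    def collect(n: LabeledTree) -> None:
        if n.is_leaf:
            leaves.append(n)
        for c in n.children:
            collect(c)

    collect(tree)
    length = len(leaves[0].label)
    states = sorted(set(site_states) | {l.label[s] for l in leaves for s in range(length)})

    def site_min(node: LabeledTree, site: int) -> dict[str, int]:
        if node.is_leaf:
            return {s: (0 if s == node.label[site] else 10**9) for s in states}
        tables = [site_min(c, site) for c in node.children]
        out = {}
        for s in states:
            total = 0
            for tab in tables:
                total += min(tab[s2] + (s2 != s) for s2 in states)
            out[s] = total
        return out

    return sum(min(site_min(tree, s).values()) for s in range(length))


def bruteforce_mp_histories(
    leaf_sequences: Mapping[str, str] | Iterable[str],
    label_collapsed: bool = False,
    max_leaves: int = 6,
    max_length: int = 12,
) -> set[History]:
    """Every maximally parsimonious history on the given leaf sequences.

    Enumerates all rooted multifurcating non-unifurcating topologies; per
    topology and per site, all internal character assignments restricted to
    the characters observed at that site among the leaves; collects every
    history achieving the global minimum Hamming weight.  With
    ``label_collapsed``, each optimum is label-collapsed before deduplication.
    Size-guarded — this is an oracle for small inputs.
    """
    if isinstance(leaf_sequences, Mapping):
        seqs = list(leaf_sequences.values())
    else:
        seqs = list(leaf_sequences)
    if len(set(seqs)) != len(seqs):
        raise DuplicateLeafError("leaf sequences must be pairwise distinct")
    if len(seqs) > max_leaves:
        raise SizeGuardError(f"{len(seqs)} leaves exceeds guard {max_leaves}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("leaf sequences must share one length")
    (length,) = lengths
    if length > max_length:
        raise SizeGuardError(f"sequence length {length} exceeds guard {max_length}")

    if len(seqs) == 1:
        return {history_from_labeled_tree(LabeledTree(seqs[0]))}

    site_states = [sorted({s[i] for s in seqs}) for i in range(length)]

    best_score: int | None = None
    optima: list[tuple[LabeledTree, list[list[dict]]]] = []
    for shape in _topologies(seqs):
        internals = _internal_nodes(shape, [])
        score = 0
        per_site: list[list[dict]] = []
        for site in range(length):
            site_best: int | None = None
            site_assignments: list[dict] = []
            for combo in product(site_states[site], repeat=len(internals)):
                assignment = {id(n): ch for n, ch in zip(internals, combo)}
                cost = _site_cost(shape, assignment, site)
                if site_best is None or cost < site_best:
                    site_best, site_assignments = cost, [assignment]
                elif cost == site_best:
                    site_assignments.append(assignment)
            score += site_best
            per_site.append(site_assignments)
        if best_score is None or score < best_score:
            best_score, optima = score, [(shape, per_site)]
        elif score == best_score:
            optima.append((shape, per_site))

    result: set[History] = set()
    for shape, per_site in optima:
        internals = _internal_nodes(shape, [])
        for site_choice in product(*per_site):
            labels = {
                id(n): "".join(site_choice[s][id(n)] for s in range(length))
                for n in internals
            }

            def relabel(node: LabeledTree) -> LabeledTree:
                if node.is_leaf:
                    return node
                return LabeledTree(
                    labels[id(node)], tuple(relabel(c) for c in node.children)
                )

            t = history_from_labeled_tree(relabel(shape))
            if label_collapsed:
                t = collapse_history(t)
            result.add(t)
    return result


# ---------------------------------------------------------------------------
# independent enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_histories_oracle(
    d: HistorySDAG, limit: int = 10_000
) -> list[History]:
    """Exhaustively enumerate the histories of an sDAG by an iterative
    frontier expansion — a traversal independent of the recursive generator
    in :mod:`histdag.core`, used to cross-validate it."""
    if d.count_histories() > limit:
        raise SizeGuardError(f"history count exceeds oracle limit {limit}")
    out: list[History] = []
    for ua_child in d.ua_children:
        stack: list[tuple[tuple, tuple]] = [((ua_child,), ((UA, ua_child),))]
        while stack:
            frontier, edges = stack.pop()
            if not frontier:
                out.append(History(edges))
                continue
            v, rest = frontier[-1], frontier[:-1]
            if v.is_leaf:
                stack.append((rest, edges))
                continue
            from .core import clade_key

            clades = sorted(v.clades, key=clade_key)
            for combo in product(
                *(d.children_of_clade(v, c) for c in clades)
            ):
                stack.append(
                    (rest + combo, edges + tuple((v, c) for c in combo))
                )
    return out
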