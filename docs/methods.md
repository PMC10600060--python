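# Methods

## The model

`histdag` operates on *histories*: rooted, multifurcating, non-unifurcating
trees in which every node, internal nodes included, carries a label from an
ambient set Y — in the parsimony setting, complete unambiguous nucleotide
sequences of one fixed length. Internal labels are data, not decoration:
they are what makes a history's parsimony score decomposable as a sum of an
edge weight (Hamming distance) over edges, independent of surrounding
structure, and they are what the subpartition-DAG encoding merges on.

A node is the pair (ℓ, U) of its label and its subpartition — the set of
descendant-leaf-label sets (clades) of its children, one clade per child,
pairwise disjoint, never exactly one in number (that restriction is what
rules out unifurcations and, with it, cycles). Leaves are (ℓ, ∅), and no two
leaves of one history may share a label: a leaf is identified by its label.
A sampled ancestor is represented as an internal node adjacent to a leaf
carrying the same label; such edges target a leaf and are therefore never
collapsed. A formal universal-ancestor (UA) node ρ, with no label, sits
above every permissible root; its out-edges record which nodes may be roots.

The subpartition of a node is redundant with the structure below it (the
reachable leaf labels of v always equal CU(v); this is validated, and
asserted as a test invariant on every generated graph), but the redundancy
is the point: it makes node identity structural, so the graph union of
histories built independently merges exactly the nodes that agree on label
*and* clade decomposition. Everything the sDAG adds beyond its inputs comes
from that merging: below a shared node, any subhistory from one input can
replace the corresponding subhistory of another.

## Choices with units and defaults

| parameter | default | meaning |
|---|---|---|
| `SimulationConfig.n_leaves` | 5 | taxa per simulated history |
| `SimulationConfig.sequence_length` | 8 | sites per label (characters) |
| `SimulationConfig.alphabet` | `ACGT` | unambiguous nucleotide states |
| `SimulationConfig.mutation_rate_per_site` | 0.1 | substitution probability per site per edge |
| `SimulationConfig.multifurcation_probability` | 0.25 | chance each extra lineage joins a merge |
| `hamming_parsimony(ua_reference=None)` | 0 on UA edges | UA edges cost nothing unless a reference sequence is supplied |
| `weight_distribution(..., max_distinct_weights)` | 10 000 | abort guard on convolution blow-up |
| `bruteforce_mp_histories` guards | ≤ 6 leaves, length ≤ 12 | exhaustive search envelope |
| `complete_sdag_on_labels` guards | ≤ 5 leaves, ≤ 6 labels | the complete sDAG is super-exponential |

The UA node has no label, so the edge weight on UA edges is a genuine
choice. The default (additive identity) makes a history's weight equal the
standard parsimony score of the corresponding tree; passing `ua_reference`
charges each root for its distance from a fixed ancestral sequence, which is
the natural scoring when an outgroup/ancestor is pinned.

The integer weight contract (nonnegative integers, ordinary addition and
order) is *clade-ordered* — its order respects addition — for any
context-free nonnegative edge function, which licenses the per-clade
minimization in the dynamic program. Custom contracts (e.g. lexicographic
tuples) are accepted, but clade-ordering cannot be verified exhaustively for
them; it is documented as a caller obligation and only the encountered
values are implicitly exercised.

## Algorithms and numerical choices

**Counting, enumeration, sampling.** Counts use exact arbitrary-precision
integers (they are astronomically large in realistic sDAGs; nothing here may
overflow). Enumeration is a lazy generator over per-clade edge choices;
sampling chooses each edge with probability proportional to the subhistory
count below its target, giving an exactly uniform draw, seeded. An
independent frontier-expansion enumerator (different traversal, different
code path) cross-validates both.

**Trimming.** One postorder pass fills M_f for every node and node-clade
pair; edges achieving the per-pair minima are kept, then nodes unreachable
from ρ through kept edges are dropped, then kept edges touching dropped
nodes are dropped. Ties are all retained — no tie-breaking, because the trim
must express *every* minimum-weight history. Weight equality is tested
through the contract's order (neither a < b nor b < a), not `==`, so
contracts with non-trivial equivalence behave consistently.

**Collapsing.** Single histories: repeatedly apply the endpoint-merging node
map; the collapsed form is unique regardless of order, so the canonical
first edge is taken (order invariance is separately tested with randomized
orders). Whole sDAGs: a queue of edges seeded in UA-first topological order;
each collapsible edge still present in the graph is replaced by a merged
parent node that inherits the parent's parents, the parent's other-clade
children and the child's children (all new edges enqueued); the parent is
removed if its pair over the collapsed clade emptied, the child if orphaned,
with recursive cleanup of unreachable descendants. Stale queue entries —
edges removed by earlier iterations — are skipped on pop. New nodes are
interned by value, so a merged parent that already exists simply gains
edges. The initial queue may be any linear extension of the
parents-before-descendant-edges order; a seeded randomizer for this order is
built in precisely so the invariance claim is testable.

**Completion.** Nodes are indexed by clade union once; each node-clade pair
then receives edges to every node with the matching union, so the cost is
proportional to the number of output edges rather than an all-pairs scan. ρ
gains edges to every node whose clade union equals that of an *existing* UA
child: completion never invents new root clade unions (nor new nodes).
Whether completion should create new root candidates is genuinely open; we
chose not to, keeping the set of permissible root leaf-sets an invariant of
the input.

**Determinism.** Every set-valued accessor iterates in a canonical sorted
order (labels by value, clades and subpartitions lexicographically, the UA
node first), so enumeration order, sampling given a seed, and the JSON
serialization are reproducible; structurally equal sDAGs serialize to
identical bytes regardless of construction order.

## Synthetic data: what it does and does not emulate

The generator grows a topology by random lineage merging (extra lineages
join a merge with the multifurcation probability), draws a random root
sequence, and mutates each site independently along each edge. At the
default 0.1 substitutions per site per edge on length-8 sequences, roughly
40% of edges carry no mutation — deliberately, since zero-mutation edges are
what label-collapsing acts on — while leaf sets still admit several distinct
parsimony optima. Duplicate leaf sequences are perturbed minimally and
deterministically until distinct. A second generator fixes the leaf set and
draws internal labels site-wise from the characters observed below, which
yields same-leaf-set history collections spanning a range of scores (the
regime where trimming is nontrivial).

This emulates none of the realities of sequence evolution — no rate
heterogeneity, no indels, no selection, no recombination — and the problem
sizes (up to ~7 leaves, lengths 4–8, a handful of input histories) are
chosen so that exhaustive oracles remain exact: every brute-force search,
enumeration and per-history comparison in the test suite is literal, not
sampled. Passing tests therefore certify the combinatorial machinery — the
structure, counting, trimming, collapsing and completion guarantees — on
small dense instances; they say nothing about inference quality on real
data, and nothing about constants at the scale of real pathogen phylogenies
(where the same guarantees hold but are only exercised here at desk scale).

## The brute-force parsimony oracle

Maximum-parsimony history sets on small inputs are found by enumerating all
rooted multifurcating non-unifurcating topologies (recursively, via set
partitions of the leaf set — mirroring the subpartition structure) and, per
topology and per site, all internal-state assignments restricted to the
characters observed at that site among the leaves. That restriction is a
standard parsimony fact (an unobserved state at a site can always be
replaced by an observed one without increasing cost); it is additionally
sanity-checked by agreement with an independent unit-cost Sankoff dynamic
program on each optimal topology. Optima are assembled per-site (a total
assignment is optimal iff it is optimal at every site, since sites
contribute independently), optionally label-collapsed, and deduplicated
structurally.

## Known limitations

* No branch lengths, clock models, or probability distributions over
  histories; weights are the only ranking notion.
* No generalized cost matrices (Sankoff-style weighted parsimony) and no
  re-optimization of ancestral labels within the sDAG: subhistory swaps keep
  the ancestral labels their source histories had.
* The JSON serialization requires string labels.
* `weight_distribution` is exact and therefore memory-bound by the number of
  distinct weights (guarded, default 10 000).
* Collapsing with a custom predicate is library-level only; the CLI fixes
  the predicate to label equality.
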