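# histdag

Compact storage and combinatorial extension of ensembles of rooted,
internally labeled phylogenetic trees, via the **history subpartition DAG**
(history sDAG).

## The problem

Maximum-parsimony reconstruction of densely sampled pathogen data (the
motivating case is SARS-CoV-2) rarely yields a single best tree: there are
typically very many trees — each with ancestral sequences inferred at every
internal node — achieving the same minimal mutation count. Working with that
uncertainty requires a structure that can *store* huge collections of such
trees, *find more* of them, and support exact counting, filtering and
sampling. `histdag` is a library (plus a small CLI) for phylogeneticists who
want to manipulate such ensembles at the level of whole collections rather
than one tree at a time.

## The structure

A **history** is a rooted, multifurcating, non-unifurcating tree with a
label (e.g. a nucleotide sequence) on *every* node. Each history node is
encoded as a pair *(ℓ, U)* of its label ℓ and its **subpartition** *U* — the
set of clades (descendant-leaf-label sets) below each of its children; a
leaf is *(ℓ, ∅)*. A formal universal-ancestor node ρ sits above every root.
The **clade union** CU(*v*) is {ℓ} for a leaf and ⋃<sub>C∈U</sub> C
otherwise.

A **history sDAG** (V, E) is any graph of such nodes in which every node is
reachable from ρ, each edge targets a node whose clade union is a child
clade of its parent, and every node-clade pair (*v*, *C*), *C* ∈ *U*, has at
least one descendant edge. A history is the special case where every choice
is unique. Because node identity is structural, the **graph union** of many
histories merges shared substructure — and in general expresses *more*
histories than it was built from, obtained by swapping subhistories below
structurally equal nodes.

Key operations, all exact:

* **count / enumerate / sample** — the number of histories in the sDAG
  follows the recursion N(leaf) = 1,
  N(*v*) = ∏<sub>C∈U</sub> Σ<sub>v<sub>c</sub>∈Ch(v,C)</sub> N(*v<sub>c</sub>*);
  sampling each edge with probability proportional to N of its target draws
  uniformly over histories.
* **minimum-weight trim** — for an edge weight function *f* (Hamming
  distance between endpoint sequences gives the parsimony score
  g<sub>f</sub>(t) = Σ<sub>e</sub> f(e)), the dynamic program
  M<sub>f</sub>(*v*, *C*) = min<sub>v<sub>c</sub></sub>
  [M<sub>f</sub>(*v<sub>c</sub>*) + f(*v*, *v<sub>c</sub>*)],
  M<sub>f</sub>(*v*) = Σ<sub>C∈U</sub> M<sub>f</sub>(*v*, *C*) computes the
  minimum weight in one postorder pass; keeping exactly the edges achieving
  the per-pair minima yields the sDAG of precisely the minimum-weight
  histories. An sDAG built from equal-weight histories either stays
  concentrated at that weight or strays both below *and* above it — so a
  union of maximally parsimonious histories contains only maximally
  parsimonious histories.
* **label-collapse** — edges joining equal non-leaf labels carry no mutation
  information; collapsing them (merging the endpoints into
  (ℓ<sub>p</sub>, U<sub>p</sub> ∪ U<sub>c</sub> ∖ {CU(v<sub>c</sub>)}))
  introduces multifurcations without changing parsimony scores, and the
  whole-sDAG algorithm produces exactly the per-history collapses.
* **completion** — adding every edge compatible with clade unions (no new
  nodes) lets any same-leaf-set subhistories swap; trimming afterwards can
  discover additional minimum-weight histories.

## Worked example

Two 4-leaf histories on leaves {A, C, G, T} (length-1 labels) share the root
node (A, {{A,C},{G,T}}) but differ in both internal children — one has
internal labels A and G, the other C and T:

```python
import histdag as hd

def build(left, right):
    leaves = {x: hd.LabeledTree(x) for x in "ACGT"}
    return hd.history_from_labeled_tree(hd.LabeledTree("A", (
        hd.LabeledTree(left,  (leaves["A"], leaves["C"])),
        hd.LabeledTree(right, (leaves["G"], leaves["T"])))))

d = hd.sdag_union([build("A", "G"), build("C", "T")])
from histdag.io import summarize
print(summarize(d))
print(summarize(hd.min_weight_trim(d, hd.hamming_parsimony())))
```

prints

```
{'nodes': 10, 'edges': 13, 'leaves': 4, 'histories': 4, 'min_weight': 3,
 'weight_distribution': {'3': 2, '4': 2}}
{'nodes': 9, 'edges': 10, 'leaves': 4, 'histories': 2, 'min_weight': 3,
 'weight_distribution': {'3': 2}}
```

The union of *two* histories expresses *four* — the two inputs plus the two
mixed choices of internal children, which arise purely from subhistory
swapping below the shared root node. Their parsimony scores are 3, 4, 4, 3
(each internal label A/C/G/T costs 0 or 1 mutations against its three
neighbors), and the minimum-weight trim retains exactly the two score-3
histories.

The same workflow from the shell:

```sh
histdag synth -n 5 -l 8 --trees 3 --seed 7 -o fix      # newick + FASTA fixtures
histdag build -t fix.nwk -s fix.fasta -o dag.json
histdag complete dag.json -o dagc.json
histdag trim dagc.json --weight parsimony -o dagt.json
histdag collapse dagt.json -o final.json
histdag summarize final.json
histdag sample final.json -n 10 --seed 1 -o samples.nwk
```

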