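"""Readers and writers: newick trees with sequence labels, and the canonical
JSON sDAG serialization.

Newick node names — internal nodes included, since internal labels are core
data here — are identifiers resolved through a companion FASTA file mapping
identifier to sequence; without a FASTA, names are taken as the labels
themselves.  Branch lengths are ignored on read and omitted on write.

The JSON format indexes labels once and lists nodes and edges in canonical
sorted order, so structurally equal sDAGs serialize to identical bytes.
"""

from __future__ import annotations

import json
import re
from typing import Iterable, Mapping

import dendropy
from Bio import SeqIO

from .core import (
    HistorySDAG,
    History,
    LabeledTree,
    SDAGNode,
    UA,
    clade_key,
    history_from_labeled_tree,
    history_to_labeled_tree,
    label_key,
    make_subpartition,
    node_key,
)
from .errors import (
    HistDagError,
    MissingSequenceError,
    ParseError,
    SchemaError,
)
from .weights import EdgeWeightFunction, hamming_parsimony, history_weight
from .weights import min_weight_table, weight_distribution
from .errors import SizeGuardError

__all__ = [
    "read_fasta",
    "read_histories",
    "write_histories",
    "read_sdag",
    "write_sdag",
    "sdag_to_json",
    "sdag_from_json",
    "summarize",
]


# ---------------------------------------------------------------------------
# newick + FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _resolve(name: str | None, sequences: Mapping[str, str] | None) -> str:
    if name is None or name == "":
        raise ParseError("every newick node (internal nodes included) must be named")
    if sequences is None:
        return name
    try:
        return sequences[name]
    except KeyError:
        raise MissingSequenceError(
            f"newick name {name!r} has no FASTA sequence"
        ) from None


def _dendropy_to_labeled_tree(
    node: dendropy.Node, sequences: Mapping[str, str] | None
) -> LabeledTree:
    name = node.taxon.label if node.taxon is not None else node.label
    label = _resolve(name, sequences)
    return LabeledTree(
        label,
        tuple(_dendropy_to_labeled_tree(c, sequences) for c in node.child_nodes()),
    )


def read_histories(
    newick_path,
    fasta_path=None,
    fixed_root_as_leaf: bool = False,
) -> list[History]:
    """One history per newick tree, in file order; node names key into the
    FASTA when one is given, otherwise names are the labels themselves."""
    sequences = read_fasta(fasta_path) if fasta_path is not None else None
    try:
        trees = dendropy.TreeList.get(
            path=str(newick_path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise ParseError(f"could not parse newick file: {exc}") from exc
    return [
        history_from_labeled_tree(
            _dendropy_to_labeled_tree(tree.seed_node, sequences),
            fixed_root_as_leaf=fixed_root_as_leaf,
        )
        for tree in trees
    ]


_NEEDS_QUOTING = re.compile(r"[\s()\[\]':;,]")


def _quote(name: str) -> str:
    if _NEEDS_QUOTING.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _labeled_tree_to_newick(node: LabeledTree, name_of) -> str:
    if node.is_leaf:
        return _quote(name_of(node.label))
    inner = ",".join(_labeled_tree_to_newick(c, name_of) for c in node.children)
    return f"({inner}){_quote(name_of(node.label))}"


def write_histories(
    histories: Iterable[History],
    newick_path,
    fasta_path=None,
) -> None:
    """Write histories as newick.  With a FASTA path, labels are replaced by
    generated identifiers (s0, s1, ...) written alongside as sequences;
    otherwise labels appear directly as (quoted) newick names."""
    histories = list(histories)
    if fasta_path is not None:
        ids: dict[str, str] = {}
        for t in histories:
            for v in t.sorted_nodes():
                if not v.is_ua and v.label not in ids:
                    ids[v.label] = f"s{len(ids)}"
        with open(fasta_path, "w") as fh:
            for label, ident in sorted(ids.items(), key=lambda kv: kv[1]):
                fh.write(f">{ident}\n{label}\n")
        name_of = ids.__getitem__
    else:
        name_of = str
    with open(newick_path, "w") as fh:
        for t in histories:
            fh.write(_labeled_tree_to_newick(history_to_labeled_tree(t), name_of) + ";\n")


# ---------------------------------------------------------------------------
# canonical JSON
# ---------------------------------------------------------------------------

def sdag_to_json(d: HistorySDAG) -> str:
    """Byte-deterministic canonical JSON for an sDAG with string labels."""
    labels = sorted(
        {v.label for v in d.nodes if not v.is_ua}, key=label_key
    )
    for l in labels:
        if not isinstance(l, str):
            raise SchemaError("JSON serialization requires string labels")
    index = {l: i for i, l in enumerate(labels)}
    nodes = d.sorted_nodes()
    node_index = {v: i for i, v in enumerate(nodes)}
    node_records = []
    for v in nodes:
        if v.is_ua:
            node_records.append({"label": None, "clades": []})
        else:
            node_records.append(
                {
                    "label": index[v.label],
                    "clades": sorted(
                        sorted(index[l] for l in clade)
                        for clade in v.clades
                    ),
                }
            )
    edges = sorted(
        [node_index[p], node_index[c]] for p, c in d.edges
    )
    return (
        json.dumps(
            {"labels": labels, "nodes": node_records, "edges": edges},
            sort_keys=True,
            separators=(",", ":"),
        )
        + "\n"
    )


def sdag_from_json(text: str) -> HistorySDAG:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from exc
    try:
        labels = data["labels"]
        node_records = data["nodes"]
        edge_records = data["edges"]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"missing field: {exc}") from exc
    if not all(isinstance(l, str) for l in labels):
        raise SchemaError("labels must be strings")
    nodes: list[SDAGNode] = []
    for rec in node_records:
        try:
            label_idx, clades = rec["label"], rec["clades"]
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"bad node record: {rec!r}") from exc
        if label_idx is None:
            nodes.append(UA)
            continue
        try:
            label = labels[label_idx]
            clade_sets = [frozenset(labels[i] for i in c) for c in clades]
        except (IndexError, TypeError) as exc:
            raise SchemaError(f"bad label index in {rec!r}") from exc
        try:
            nodes.append(SDAGNode(label, make_subpartition(clade_sets)))
        except HistDagError as exc:
            raise SchemaError(f"invalid subpartition: {exc}") from exc
    try:
        edges = [(nodes[p], nodes[c]) for p, c in edge_records]
    except (IndexError, TypeError, ValueError) as exc:
        raise SchemaError(f"bad edge record: {exc}") from exc
    d = HistorySDAG(edges)
    violations = d.validate()
    if violations:
        raise SchemaError(
            "serialized graph is not a valid sDAG: "
            + "; ".join(v.code for v in violations)
        )
    return d


def write_sdag(d: HistorySDAG, path) -> None:
    with open(path, "w") as fh:
        fh.write(sdag_to_json(d))


def read_sdag(path) -> HistorySDAG:
    with open(path) as fh:
        return sdag_from_json(fh.read())


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(d: HistorySDAG, f: EdgeWeightFunction | None = None) -> dict:
    """Node/edge counts, exact history count, minimum weight and (guarded)
    weight distribution of an sDAG."""
    if f is None:
        f = hamming_parsimony()
    report = {
        "nodes": len(d.nodes),
        "edges": len(d.edges),
        "leaves": len(d.leaf_nodes()),
        "histories": d.count_histories(),
        "min_weight": min_weight_table(d, f).ua_min,
    }
    try:
        dist = weight_distribution(d, f)
        report["weight_distribution"] = {
            str(w): n for w, n in sorted(dist.items())
        }
    except SizeGuardError:
        report["weight_distribution"] = None
    return report
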