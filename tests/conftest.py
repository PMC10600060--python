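import random

import pytest

import histdag as hd
from histdag import synthetic as sy


def make_four_leaf_history(left_label: str, right_label: str) -> hd.History:
    """A 4-leaf history rooted at (A, {{A,C},{G,T}}) with internal children
    labeled ``left_label`` (over {A,C}) and ``right_label`` (over {G,T})."""
    leaves = {x: hd.LabeledTree(x) for x in "ACGT"}
    left = hd.LabeledTree(left_label, (leaves["A"], leaves["C"]))
    right = hd.LabeledTree(right_label, (leaves["G"], leaves["T"]))
    return hd.history_from_labeled_tree(hd.LabeledTree("A", (left, right)))


@pytest.fixture
def four_history_inputs():
    """Two histories sharing their root node but differing in both internal
    children; their union expresses all four combinations."""
    return make_four_leaf_history("A", "G"), make_four_leaf_history("C", "T")


@pytest.fixture
def four_history_union(four_history_inputs):
    return hd.sdag_union(list(four_history_inputs))


@pytest.fixture
def cherry():
    """Smallest nontrivial history: root AA with leaf children AA and AC."""
    return hd.history_from_labeled_tree(
        hd.LabeledTree("AA", (hd.LabeledTree("AA"), hd.LabeledTree("AC")))
    )


def random_sdag(seed: int, n_leaves: int = 4, length: int = 5, n_histories: int = 3):
    cfg = sy.SimulationConfig(
        n_leaves=n_leaves, sequence_length=length, seed=seed
    )
    return sy.random_sdag(cfg, n_histories)


def random_leaf_sequences(
    rng: random.Random, n: int, length: int, rate: float = 0.25
) -> list[str]:
    """Distinct sequences clustered around a random ancestor."""
    root = "".join(rng.choice("ACGT") for _ in range(length))
    seqs: set[str] = set()
    while len(seqs) < n:
        seqs.add(
            "".join(
                c if rng.random() > rate else rng.choice("ACGT") for c in root
            )
        )
    return sorted(seqs)
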