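"""Exception hierarchy shared across the package."""


class HistDagError(Exception):
    """Base class for all histdag errors."""


class SubpartitionError(HistDagError):
    """A set of clades is not a valid subpartition."""


class SingletonSubpartitionError(SubpartitionError):
    """A subpartition may not contain exactly one clade."""


class OverlappingCladesError(SubpartitionError):
    """Clades in a subpartition must be pairwise disjoint."""


class EmptyCladeError(SubpartitionError):
    """Clades in a subpartition must be nonempty."""


class UANodeError(HistDagError):
    """Operation undefined for the universal-ancestor node."""


class UnifurcationError(HistDagError):
    """Input tree contains a node with exactly one child."""


class DuplicateLeafError(HistDagError):
    """Two leaves of one tree carry the same label."""


class NotAHistoryError(HistDagError):
    """Structure does not satisfy the definition of a history."""


class InvalidSDAGError(HistDagError):
    """Structure does not satisfy the definition of a history sDAG."""


class SizeGuardError(HistDagError):
    """Requested computation exceeds a configured size guard."""


class LengthMismatchError(HistDagError):
    """Sequence labels on an edge have different lengths."""


class AmbiguousCharacterError(HistDagError):
    """Sequence label contains a character outside the unambiguous alphabet."""


class LeafTargetError(HistDagError):
    """Edges whose target is a leaf node cannot be collapsed."""


class NotAnEdgeError(HistDagError):
    """The named edge is not present in the structure."""


class UAParentError(HistDagError):
    """Edges descending from the universal-ancestor node cannot be collapsed."""


class MissingSequenceError(HistDagError):
    """A newick node name does not resolve to a FASTA sequence."""


class ParseError(HistDagError):
    """Input file could not be parsed."""


class SchemaError(HistDagError):
    """Serialized sDAG violates the canonical JSON schema."""
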