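"""Exception hierarchy for the pieces package."""


class PiecesError(Exception):
    """Base class for all package-specific errors."""


class NewickError(PiecesError):
    """Malformed Newick input (message carries the parser's position info)."""


class TreeStructureError(PiecesError):
    """A tree violates a structural precondition (duplicate tips, too few tips...)."""


class GraftError(PiecesError):
    """A taxon could not be attached: unresolvable genus/family or name collision."""


class TraitError(PiecesError):
    """A binary trait is incomplete over the tips or constant."""


class TableError(PiecesError):
    """A taxon table violates its schema (unknown rank, negative count...)."""


class MatrixError(PiecesError):
    """An AHP pairwise-comparison matrix violates reciprocity/positivity."""
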