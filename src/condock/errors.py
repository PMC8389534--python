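"""Exception hierarchy shared across the toolkit."""


class CondockError(Exception):
    """Base class for all toolkit errors."""


class EmptyStructureError(CondockError):
    """A file or selection yielded no protein atoms."""


class RosterError(CondockError):
    """Atom rosters disagree where identical rosters are required."""


class ManifestError(CondockError):
    """A pose manifest is malformed (duplicates, missing columns, empty)."""


class MatrixError(CondockError):
    """An RMSD matrix is not symmetric, has NaNs, or a non-zero diagonal."""


class DegenerateSuperpositionError(CondockError):
    """Fewer than 3 paired atoms, or a collinear point set."""


class PartitionError(CondockError):
    """A chain partition is empty on one side or not disjoint."""


class GraftError(CondockError):
    """A grafting step could not align its shared domain."""


class RecipeError(CondockError):
    """A synthetic-pool recipe is infeasible."""
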