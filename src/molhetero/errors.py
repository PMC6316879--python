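"""Exception hierarchy for molhetero.

All package-specific failures derive from :class:`MolHeteroError` so callers
can catch one base class at workflow boundaries.
"""


class MolHeteroError(Exception):
    """Base class for all molhetero errors."""


class InvalidSmilesError(MolHeteroError):
    """A SMILES string could not be parsed into a molecule."""


class EmptyCorpusError(MolHeteroError):
    """An alphabet was requested for an empty corpus."""


class UnknownTokenError(MolHeteroError):
    """A SMILES contains a token absent from the alphabet."""


class LengthError(MolHeteroError):
    """A sequence does not fit within the configured maximum length."""


class MissingPropertyError(MolHeteroError):
    """An atomic property value is unavailable for a requested element."""


class GridOverflowError(MolHeteroError):
    """A molecule does not fit in the image grid at the given resolution."""


class CellCollisionError(MolHeteroError):
    """Two atoms discretize to the same image cell."""


class ConfigError(MolHeteroError):
    """Inconsistent or invalid model/experiment configuration."""


class DivergenceError(MolHeteroError):
    """Training produced a non-finite loss."""


class NotTrainedError(MolHeteroError):
    """An operation requiring trained weights was called on an untrained model."""


class StateError(MolHeteroError):
    """The stateful step decoder was used before its states were initialized."""


class DimensionError(MolHeteroError):
    """Vector dimensions do not match."""


class DegenerateDataError(MolHeteroError):
    """Data has zero variance where variation is required."""


class EmptyFixtureError(MolHeteroError):
    """A fixture specification admits no molecules."""


class SearchFailedError(MolHeteroError):
    """Every candidate in a hyperparameter search produced a NaN loss."""
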