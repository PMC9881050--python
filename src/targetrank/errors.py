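"""Named exceptions raised by targetrank.

Every error condition documented in the public API maps to one of these
classes so callers can catch them precisely instead of matching message
strings.
"""


class TargetRankError(Exception):
    """Base class for all targetrank errors."""


class InvalidSequenceError(TargetRankError):
    """Sequence contains a letter outside the accepted amino-acid alphabet."""


class EmptySequenceError(TargetRankError):
    """An operation that needs at least one residue received an empty sequence."""


class UndefinedScoreError(TargetRankError):
    """The requested score is mathematically undefined for this input."""


class InvalidCountError(TargetRankError):
    """A count that must be non-negative was negative."""


class InvalidInputError(TargetRankError):
    """Generic invalid argument (e.g., empty disease gene set)."""


class DuplicateIdError(TargetRankError):
    """Two records share an identifier that must be unique."""


class UnknownNodeError(TargetRankError):
    """A node queried on a network is not part of it."""


class InsufficientUniverseError(TargetRankError):
    """Not enough eligible proteins to draw a negative set of the requested size."""


class ConstantFeatureError(TargetRankError):
    """A feature with a single observed value cannot be discretized."""


class ShapeError(TargetRankError):
    """Vector lengths (or matrix shapes) do not agree."""


class MissingLabelsError(TargetRankError):
    """Fitting requires at least one labeled positive and one labeled negative."""


class ModelStateError(TargetRankError):
    """The model must be fitted before this operation."""


class SchemaError(TargetRankError):
    """A required column/feature is absent from the supplied table."""


class RangeError(TargetRankError):
    """A size or index parameter is outside its admissible range."""


class DegenerateLabelsError(TargetRankError):
    """ROC evaluation needs both classes present among the labels."""


class InsufficientDataError(TargetRankError):
    """Too few labeled proteins for the requested cross-validation scheme."""


class LeakageError(TargetRankError):
    """Training and independent-test positives overlap."""


class ConfigError(TargetRankError):
    """A synthetic-genome generator configuration is infeasible."""
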