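"""Exception hierarchy shared across the package."""


class RnaMotifsError(Exception):
    """Base class for all package errors."""


class InvalidCharacterError(RnaMotifsError):
    """A dot-bracket string contains a character outside {., (, )}."""


class UnbalancedBracketsError(RnaMotifsError):
    """A dot-bracket string has an unmatched '(' or ')'."""


class PseudoknotError(RnaMotifsError):
    """A pair table violates the nested (pseudoknot-free) property."""


class AlphabetError(RnaMotifsError):
    """A sequence contains residues outside {A, C, G, U}."""


class EngineUnavailableError(RnaMotifsError):
    """The requested folding engine cannot be loaded at runtime."""


class LimitExceededError(RnaMotifsError):
    """An exhaustive enumeration was requested above the safety guard."""


class UnsupportedLevelError(RnaMotifsError):
    """A shape-abstraction level outside the supported range was requested."""


class InvalidCompositionError(RnaMotifsError):
    """Nucleotide composition probabilities are negative or do not sum to 1."""


class EmptyInputError(RnaMotifsError):
    """An operation received an empty collection where data is required."""


class InsufficientOverlapError(RnaMotifsError):
    """Too few shapes are shared between two ensembles to correlate."""


class DegenerateDesignError(RnaMotifsError):
    """A regression design has no length variation (or too few points)."""


class SingleClassError(RnaMotifsError):
    """A classification routine received labels from a single class."""


class KTooLargeError(RnaMotifsError):
    """kNN neighbour count exceeds the smallest training-fold class size."""
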