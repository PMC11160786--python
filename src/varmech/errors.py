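"""Exception hierarchy shared across the package."""


class VarmechError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VarmechError):
    """A file could not be parsed in the expected format."""


class EmptyInputError(VarmechError):
    """An operation received an empty chain, table or list."""


class ValidationError(VarmechError):
    """An argument violated a documented precondition."""


class DegenerateInputError(VarmechError):
    """Input is formally valid but the statistic is undefined on it
    (all-zero contingency table, constant vector, ...)."""


class UndefinedAUCError(DegenerateInputError):
    """Labels contain a single class; the ROC AUC does not exist."""


class ConstructionError(VarmechError):
    """A synthetic geometry could not be realised within bounded retries."""


class InsufficientDataError(VarmechError):
    """Fewer observations than the operation needs (e.g. < 3 joined rows
    for a correlation, fewer partners than ``min_partners``)."""
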