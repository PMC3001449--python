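"""Exception hierarchy.

Every error raised by the package derives from :class:`BisensError` so that
callers (and the CLI, which maps validation errors to exit code 2 and
insufficient-data errors to exit code 3) can distinguish the failure class.
"""


class BisensError(Exception):
    """Base class for all package errors."""


class FormatError(BisensError, ValueError):
    """An on-disk file does not conform to the documented dialect."""


class PDBParseError(FormatError):
    """A PDB record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(BisensError, ValueError):
    """An in-memory record violates a domain invariant."""


class EmptyStructureError(ValidationError):
    """No CA atoms found within the requested domain range."""


class UndefinedStatisticError(BisensError, ZeroDivisionError):
    """A statistic is undefined for the given input (e.g. N_algn = 0)."""


class InsufficientDataError(BisensError):
    """Too few observations for the requested fit or test."""


class SingularFitError(BisensError):
    """The regression design matrix is singular (perfect co-linearity)."""

    def __init__(self, message: str, predictor_correlation: float | None = None):
        self.predictor_correlation = predictor_correlation
        super().__init__(message)


class GroupingError(BisensError, ValueError):
    """A grouping produced an empty group."""


class ScenarioError(BisensError, ValueError):
    """A simulation scenario is self-contradictory or out of range."""
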