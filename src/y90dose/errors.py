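"""Exception hierarchy.

Validation problems (bad user input, mismatched geometry) derive from
:class:`ValidationError`; failures arising during a computation derive from
:class:`ComputationError`.  The CLI maps the two branches to distinct exit
codes.
"""


class Y90DoseError(Exception):
    """Base class for all package errors."""


class ValidationError(Y90DoseError, ValueError):
    """Invalid or inconsistent input."""


class InvalidInputError(ValidationError):
    """A scalar argument is out of its admissible range."""


class GridMismatchError(ValidationError):
    """Images or masks do not share the same grid / alignment frame."""


class ZeroVolumeError(ValidationError):
    """An operation received an empty VOI where a volume is required."""


class InconsistencyError(ValidationError):
    """Compartment bookkeeping violated (e.g. lesion counts exceed liver counts)."""


class IncompleteCaseError(ValidationError):
    """A report was requested from a case record lacking the needed session."""


class ReconciliationError(ValidationError):
    """Pre/post compartment names cannot be matched for verification."""

    def __init__(self, message, unmatched=()):
        super().__init__(message)
        self.unmatched = tuple(unmatched)


class ComputationError(Y90DoseError, RuntimeError):
    """A computation failed on otherwise valid input."""


class ConvergenceError(ComputationError):
    """Adaptive thresholding could not match the target volume."""


class UndefinedLSFError(ComputationError):
    """Lung shunt fraction undefined (no counts in lung nor liver)."""


class ExportOverflowError(ComputationError):
    """Integer dose-map export would overflow the requested bit width."""

    def __init__(self, message, max_representable_gy=None):
        super().__init__(message)
        self.max_representable_gy = max_representable_gy
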