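"""Exception hierarchy for shelterlos.

Validation failures (bad input data, misaligned periods, schema problems)
raise :class:`ValidationError`; statistical failures (non-convergence,
separation) raise :class:`StatisticalError`.  The CLI maps these to exit
codes 2 and 3 respectively.
"""


class ShelterLOSError(Exception):
    """Base class for all shelterlos errors."""


class ValidationError(ShelterLOSError, ValueError):
    """Invalid input data or configuration."""


class SchemaError(ValidationError):
    """A required column is missing from an input table."""


class AlignmentError(ValidationError):
    """Period boundaries do not align to whole months."""


class IdentityError(ShelterLOSError):
    """A period-boundary bookkeeping identity failed."""


class StatisticalError(ShelterLOSError, RuntimeError):
    """A statistical procedure could not produce a valid result."""


class ConvergenceError(StatisticalError):
    """Newton-Raphson failed to converge."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class SeparationError(StatisticalError):
    """Monotone partial likelihood (a covariate perfectly orders events)."""
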