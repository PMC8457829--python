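"""Exception hierarchy.

All errors raised on bad *input* derive from :class:`ValueError` so that
callers doing generic validation can catch them uniformly; failures of the
numerics themselves derive from :class:`RuntimeError`.
"""


class MorphocostError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MorphocostError, ValueError):
    """A model parameter is non-finite, non-positive or otherwise illegal."""


class DomainError(MorphocostError, ValueError):
    """A position/grid argument lies outside the spatial domain."""


class SingularInputError(MorphocostError, ValueError):
    """The requested quantity diverges at this input (e.g. zero slope)."""


class ValidityError(MorphocostError, ValueError):
    """Input violates a stated validity regime of an asymptotic formula."""


class MissingParameterError(MorphocostError, ValueError):
    """A required field is absent from a record or config."""


class NumericalError(MorphocostError, RuntimeError):
    """An optimizer or solver failed to converge."""


class NoSteadyStateError(MorphocostError, RuntimeError):
    """The dynamical system has no (finite) stationary state."""


class ResourceBudgetError(MorphocostError, RuntimeError):
    """An exact simulation would exceed the configured event budget."""


class EstimationError(MorphocostError, ValueError):
    """Not enough data to form the requested statistical estimate."""
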