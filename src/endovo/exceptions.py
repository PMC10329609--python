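"""Exception types shared across the package."""


class EndovoError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(EndovoError, ValueError):
    """An argument violates a documented precondition."""


class BranchError(EndovoError, ValueError):
    """The requested quantity is outside the well-defined branch
    (e.g. the SO(3) logarithm at rotation angles >= pi)."""


class DegenerateProblemError(EndovoError, RuntimeError):
    """The pose problem has no usable pixels (empty residual support)."""


class StationarityError(EndovoError, RuntimeError):
    """Implicit differentiation was requested at a point that is not a
    stationary point of the objective."""


class EmptyBatchError(EndovoError, RuntimeError):
    """No element of a training batch produced a usable gradient."""


class FormatError(EndovoError, ValueError):
    """A file does not conform to the expected on-disk format."""
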