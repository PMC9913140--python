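"""Exception hierarchy shared across the package."""


class AoadlError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AoadlError, ValueError):
    """An argument violates a documented precondition."""


class StructuralError(AoadlError, ValueError):
    """Shapes or sizes of model pieces are mutually inconsistent."""


class NumericalError(AoadlError, ArithmeticError):
    """A computation produced a non-finite or otherwise unusable value."""


class ObjectiveError(AoadlError, RuntimeError):
    """A black-box objective returned a non-finite value.

    Carries the offending position so the caller can reproduce the failure.
    """

    def __init__(self, message: str, position=None):
        super().__init__(message)
        self.position = position
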