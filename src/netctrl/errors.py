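"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class StabilityError(ValueError):
    """Raised when an operation requires a Hurwitz (stable) matrix and got one
    whose spectral abscissa is not safely negative."""


class NotTargetControllableError(ValueError):
    """The target Gramian is numerically singular; steering is impossible.

    Carries the offending minimum eigenvalue in ``lambda_min``.
    """

    def __init__(self, message: str, lambda_min: float):
        super().__init__(message)
        self.lambda_min = lambda_min
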