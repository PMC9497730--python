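"""Exception types raised across the package."""


class CartidiffError(Exception):
    """Base class for package-specific errors."""


class FitConvergenceError(CartidiffError):
    """A nonlinear fit failed to converge after bounded restarts.

    Carries the attempted initializations so the failure is diagnosable;
    never raised silently in place of a degraded result.
    """

    def __init__(self, message: str, attempts=None):
        super().__init__(message)
        self.attempts = attempts or []
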