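"""Exception hierarchy shared by all analysis stages."""


class SuprafitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SuprafitError, ValueError):
    """Raised when data or parameters violate a documented precondition."""


class InvalidModelError(SuprafitError, ValueError):
    """Raised when a model object is internally inconsistent (e.g. tau <= 0)."""


class FitFailureError(SuprafitError, RuntimeError):
    """Raised when an optimizer fails to converge.

    Carries ``best_result`` (whatever the optimizer last produced) so callers
    can inspect the failed fit.
    """

    def __init__(self, message, best_result=None):
        super().__init__(message)
        self.best_result = best_result


class NumericalError(SuprafitError, RuntimeError):
    """Raised when an iterative numerical scheme fails to reach tolerance."""


class ConfigurationError(SuprafitError, ValueError):
    """Raised for malformed pipeline/CLI configuration."""
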