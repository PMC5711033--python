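"""Exception hierarchy used across the package.

All exceptions derive from :class:`CausaldirError` so callers can catch
package errors with a single ``except`` clause, while still being
``ValueError`` subclasses for idiomatic use.
"""


class CausaldirError(ValueError):
    """Base class for all causaldir errors."""


class ConfigurationError(CausaldirError):
    """A table dialect, grid or option is mis-specified."""


class ValidationError(CausaldirError):
    """Input data violate a documented contract (e.g. p-value out of range)."""


class DomainError(CausaldirError):
    """A numeric argument is outside the mathematical domain of an operation."""


class DegenerateInputError(CausaldirError):
    """Inputs are formally valid but make the statistic undefined
    (zero variance, perfect collinearity, |r| = 1, zero instrument effect)."""
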