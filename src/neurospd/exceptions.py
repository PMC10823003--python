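"""Exception hierarchy.

Three failure families: bad configuration (caller error, detectable before any
computation), bad data (a recording or matrix that violates a precondition),
and numerical breakdown (non-finite values, failed decompositions).
"""


class NeurospdError(Exception):
    """Base class for all package errors."""


class ConfigError(NeurospdError, ValueError):
    """Invalid configuration or parameters (wrong dims, bad threshold, unknown kind)."""


class DataError(NeurospdError, ValueError):
    """Input data violates a precondition (constant signal, short trial, ...)."""


class NotSPDError(NeurospdError, ValueError):
    """A matrix expected to be symmetric positive definite is not."""


class NumericalError(NeurospdError, ArithmeticError):
    """Non-finite values or a failed decomposition."""
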