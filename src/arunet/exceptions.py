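"""Exception types shared across the package."""


class ArunetError(Exception):
    """Base class for all package errors."""


class ParameterError(ArunetError, ValueError):
    """An operation was called with an invalid parameter value."""


class ConfigurationError(ArunetError, ValueError):
    """Model or pipeline configuration is inconsistent (shapes, variants, ...)."""


class DataError(ArunetError, ValueError):
    """Input data violates a contract (shape, range, missing files, ...)."""
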