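"""Exception hierarchy shared across the package."""


class EmbryoscopeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmbryoscopeError, ValueError):
    """Invalid configuration (bad stage range, non-positive volume, ...)."""


class DomainError(EmbryoscopeError, ValueError):
    """An operation received values outside its mathematical domain."""


class InsufficientDataError(EmbryoscopeError, ValueError):
    """Not enough observations to perform the requested fit/selection."""
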