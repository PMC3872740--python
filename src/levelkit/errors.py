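"""Exception hierarchy shared across the toolkit."""


class LevelSetError(Exception):
    """Base class for all levelkit errors."""


class DomainError(LevelSetError):
    """A grid index lies outside the registered domain."""


class ConfigurationError(LevelSetError):
    """Invalid assembly: unknown quantity, empty equation, bad config key."""


class DegenerateInputError(LevelSetError):
    """Input with no usable structure (all-foreground mask, empty region, ...)."""


class NumericalError(LevelSetError):
    """Non-finite values produced during evolution."""


class IdError(LevelSetError, KeyError):
    """Duplicate or missing identifier in a container."""


class HandleError(LevelSetError):
    """Invalid or already-released observer handle."""
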