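"""Exception types shared across the package."""


class MishError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MishError):
    """A required column, parameter, or path is missing or malformed."""


class DataError(MishError):
    """Input data violate an invariant (negative counts, duplicates, ...)."""
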