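"""Exception hierarchy shared across the package."""


class NegaProcessError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NegaProcessError):
    """A file does not conform to the expected dialect (missing columns, bad rows)."""


class ValidationError(NegaProcessError):
    """Parsed content violates a domain invariant (unknown dye, bad marker, ...)."""


class InsufficientDataError(NegaProcessError):
    """Too few observations to compute the requested statistic."""


class ConfigurationError(NegaProcessError):
    """A required configuration item (threshold, ILS definition, ...) is missing."""
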