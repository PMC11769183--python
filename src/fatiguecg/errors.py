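"""Exception hierarchy shared across the pipeline stages."""


class FatigueCGError(ValueError):
    """Base class for all package-specific errors."""


class InvalidParameterError(FatigueCGError):
    """A configuration or generator parameter is out of its valid range."""


class InvalidInputError(FatigueCGError):
    """A data input violates a stage precondition (length, range, vocabulary)."""


class DegenerateInputError(InvalidInputError):
    """Input is structurally valid but degenerate (e.g. zero variance)."""


class ConfigError(FatigueCGError):
    """A model/harness configuration is inconsistent."""
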