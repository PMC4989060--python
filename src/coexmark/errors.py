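"""Exception types shared across the pipeline."""


class CoexmarkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CoexmarkError, ValueError):
    """A configuration value is out of its documented range."""


class FormatError(CoexmarkError, ValueError):
    """An input file does not conform to its documented dialect."""
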