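"""Exception hierarchy shared across the pipeline."""


class MadwearError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MadwearError, ValueError):
    """A sensor file could not be parsed."""


class MalformedPayloadError(FormatError):
    """Binary accelerometer payload violates the trifecta layout."""


class HeaderError(FormatError):
    """Header file is missing required metadata or is inconsistent."""


class ParseError(FormatError):
    """Text dialect (CSV/header) could not be parsed."""


class ConfigError(MadwearError, ValueError):
    """Invalid analysis configuration (epoch lengths, thresholds, ...)."""
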