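"""Exception hierarchy for the gait pipeline."""


class GaitError(Exception):
    """Base class for all pipeline errors."""


class FormatError(GaitError):
    """A file does not follow the expected dialect (e.g. missing columns)."""


class ParseError(GaitError):
    """A cell or line could not be parsed; carries the offending location."""


class EmptyInputError(GaitError):
    """An input that must contain data is empty."""


class ValidationError(GaitError):
    """An in-memory object violates its invariants."""


class TooShortError(GaitError):
    """A time series is shorter than the operation requires."""


class MissingOrientationError(GaitError):
    """A record yielded no segments for one walking orientation."""


class ConfigError(GaitError):
    """A configuration value is out of its valid range."""
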