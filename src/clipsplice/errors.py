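"""Exception types shared across the package."""


class ClipspliceError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ClipspliceError):
    """A configuration value is invalid or internally inconsistent."""


class SizingError(ConfigError):
    """A simulated genome cannot host the requested genes."""


class GtfParseError(ClipspliceError):
    """A GTF record could not be parsed.

    Carries the 1-based line number of the offending record.
    """

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class AnnotationError(ClipspliceError):
    """The annotation model violates a structural constraint."""


class ConsistencyError(ClipspliceError):
    """Inputs that must describe the same underlying objects disagree."""
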