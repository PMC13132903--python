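"""Exception hierarchy for the socialfly pipeline."""


class SocialflyError(Exception):
    """Base class for all package errors."""


class ConfigError(SocialflyError):
    """Invalid arena, photoperiod, or threshold configuration."""


class ParseError(SocialflyError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class ValidationError(SocialflyError):
    """Input parsed but violates a domain invariant."""


class UndefinedMetricError(SocialflyError):
    """A metric is undefined for this input (e.g. zero total eggs)."""


class SpecError(SocialflyError):
    """Invalid synthetic-data specification."""
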