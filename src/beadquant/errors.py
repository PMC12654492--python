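"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A parameter or domain object violates its invariants."""


class ImageSizeError(ValueError):
    """An image is too small (or has the wrong number of channels) for the operation."""


class ParseError(ValueError):
    """An annotation/detection file could not be parsed.

    Carries the 1-based line number of the offending line when applicable.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class MeasurementError(ValueError):
    """A circular ROI contains no measurable pixel."""
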