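"""Exception hierarchy for screen analysis failures."""


class ScreenError(Exception):
    """Base class for all platescreen errors."""


class DesignError(ScreenError):
    """Infeasible screen layout (too many genes/controls for the plate geometry)."""


class InputValidationError(ScreenError, ValueError):
    """Malformed numeric input (non-finite values, empty vectors, bad ranges)."""


class DegeneratePlateError(ScreenError):
    """A plate cannot be normalized: under-observed rows/columns or zero residual MAD."""


class DegenerateControlError(ScreenError):
    """Control wells carry no usable spread (e.g. SD of mock z-scores is zero)."""


class TableFormatError(ScreenError):
    """A CSV table violates its dialect; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
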