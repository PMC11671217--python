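"""Exception types shared across the package."""


class PleurasegError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PleurasegError, ValueError):
    """A configuration value is invalid or degenerate; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ShapeMismatchError(PleurasegError, ValueError):
    """Two grids that must share a shape do not."""


class FormatError(PleurasegError, ValueError):
    """A file or encoding violates its format contract."""


class UndefinedRateError(PleurasegError, ZeroDivisionError):
    """A confusion-matrix rate has a zero denominator; names the rate."""

    def __init__(self, rate: str):
        self.rate = rate
        super().__init__(f"rate '{rate}' is undefined (zero denominator)")


class TrainingError(PleurasegError, RuntimeError):
    """Training aborted (empty split, non-finite loss, degenerate labels)."""
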